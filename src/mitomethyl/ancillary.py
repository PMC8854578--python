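"""Small bespoke quantifications: SILAC mixing/enrichment, qPCR, climbing.

Three self-contained analyses share this module:

* **qDGMS** (quantitative density-gradient mass spectrometry): SILAC
  heavy/light ratios across sucrose-gradient fractions are corrected
  for imperfect 1:1 mixing by the median ratio of a whole-cell lysate
  mix, then summarised per protein as the average log2 enrichment over
  two reciprocal labelling experiments (the label-swapped orientation
  is sign-flipped before averaging) and per ribosomal subunit by the
  median.

* **Efficiency-corrected comparative Ct** (Pfaffl): relative transcript
  level = E_t^(dCt_target) / E_ref^(dCt_reference), with per-amplicon
  amplification efficiencies (fold per cycle, e.g. 1.93 and 1.95) and
  the control-group mean Ct values as calibrator.

* **Climbing index**: in a five-chamber counter-current negative-
  geotaxis apparatus, flies ending in chamber k have completed k
  successful climbs; the index is the weighted performance normalised
  to the maximum possible score, sum(k * c_k) / (K * N).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SILAC_COLUMNS = ("protein", "subunit", "fraction", "ratio", "orientation")


def _check_silac(table: pd.DataFrame) -> None:
    missing = set(SILAC_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"SILAC table missing columns: {sorted(missing)}")
    if (table["ratio"] <= 0).any():
        raise ValueError("SILAC ratios must be strictly positive")


def correct_mixing(table: pd.DataFrame, whole_cell_median: float) -> pd.DataFrame:
    """Divide every heavy/light ratio by the whole-cell-mix median ratio.

    The whole-cell median captures the deviation of the actual mixing
    from 1:1; correcting by m1 then m2 equals correcting by m1*m2.
    """
    _check_silac(table)
    if whole_cell_median <= 0:
        raise ValueError(
            f"whole-cell median must be positive, got {whole_cell_median}"
        )
    out = table.copy()
    out["ratio"] = out["ratio"] / whole_cell_median
    return out


def subunit_enrichment(
    corrected: pd.DataFrame, log_space: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-protein enrichment averaged over reciprocal labelling experiments.

    In the forward orientation the condition of interest carries the
    heavy label; in the swapped orientation it carries the light label,
    so that orientation's log2 ratio is sign-flipped before averaging.
    Proteins observed in only one orientation are reported with
    ``complete = False``.  A protein quantified in several fractions is
    first summarised (mean log2 ratio) within each orientation.

    Returns the per-protein table (protein, subunit, enrichment_log2,
    complete) and the per-subunit median enrichment.  With
    ``log_space=False`` the orientation average is taken on the linear
    ratios (swapped orientation reciprocated) and then log2-transformed.
    """
    _check_silac(corrected)
    bad = set(corrected["orientation"]) - {"forward", "swapped"}
    if bad:
        raise ValueError(f"unknown label orientations: {sorted(bad)}")
    rows = []
    for (protein, subunit), grp in corrected.groupby(["protein", "subunit"]):
        per_orient: dict[str, float] = {}
        for orient, og in grp.groupby("orientation"):
            log2r = np.log2(og["ratio"]).mean()
            per_orient[orient] = float(log2r)
        oriented = []
        for orient, log2r in per_orient.items():
            oriented.append(-log2r if orient == "swapped" else log2r)
        if log_space:
            enrichment = float(np.mean(oriented))
        else:
            enrichment = float(np.log2(np.mean([2.0 ** v for v in oriented])))
        rows.append({
            "protein": protein,
            "subunit": subunit,
            "enrichment_log2": enrichment,
            "complete": len(per_orient) == 2,
        })
    per_protein = pd.DataFrame(
        rows, columns=["protein", "subunit", "enrichment_log2", "complete"]
    )
    per_subunit = per_protein.groupby("subunit")["enrichment_log2"].median()
    return per_protein, per_subunit


def relative_expression(
    measurements: pd.DataFrame,
    efficiency_target: float,
    efficiency_reference: float,
) -> pd.DataFrame:
    """Efficiency-corrected comparative-Ct relative transcript levels.

    ``measurements`` needs columns sample, group ('control' or 'test'),
    ct_target and ct_reference (each the mean of technical replicates).
    The calibrator Ct for each amplicon is the control-group mean, so

        level = E_t^(Ct_t,cal - Ct_t) / E_ref^(Ct_ref,cal - Ct_ref)

    and the control group has geometric-mean level exactly 1 by
    construction.  Efficiencies are fold amplification per cycle and
    must lie in (1, 2].
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    for name, eff in (("target", efficiency_target),
                      ("reference", efficiency_reference)):
        if not (1.0 < eff <= 2.0):
            raise ValueError(
                f"{name} efficiency must be in (1, 2], got {eff}"
            )
    if measurements[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    if (measurements[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    control = measurements[measurements["group"] == "control"]
    if control.empty:
        raise ValueError("control group is empty")
    cal_t = control["ct_target"].mean()
    cal_ref = control["ct_reference"].mean()
    out = measurements.copy()
    out["level"] = (
        efficiency_target ** (cal_t - out["ct_target"])
        / efficiency_reference ** (cal_ref - out["ct_reference"])
    )
    return out


def climbing_index(counts: Sequence[float], n_chambers: int = 5) -> float:
    """Normalised weighted climbing performance in [0, 1].

    ``counts[k]`` is the number of flies that completed exactly ``k``
    successful climbs, ``k = 0..n_chambers``; the weight of a fly is its
    climb count, and the total is normalised by the maximum possible
    score ``n_chambers * N``.
    """
    c = np.asarray(counts, dtype=float)
    if len(c) != n_chambers + 1:
        raise ValueError(
            f"expected {n_chambers + 1} chamber counts, got {len(c)}"
        )
    if (c < 0).any():
        raise ValueError("chamber counts must be non-negative")
    N = c.sum()
    if N == 0:
        raise ValueError("no flies counted")
    k = np.arange(n_chambers + 1)
    return float((k * c).sum() / (n_chambers * N))
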