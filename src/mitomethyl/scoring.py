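"""Per-position methylation scores and replicate-level differential calling.

Two orthogonal signals identify a 2'-O-methylated ribose at nucleotide
``i``:

* **Cleavage protection ("score A").**  The 2'-O-methyl group renders
  the phosphodiester bond 3' of the ribose resistant to alkaline
  hydrolysis, so in an alkaline-fragmentation library the bond's
  cleavage count ``n_i`` is depleted relative to its flanks.  With
  ``m_L, s_L`` (``m_R, s_R``) the mean and population standard
  deviation of ``n`` over the ``w`` bonds left (right) of ``i``::

      A_i = max(0, 1 - (2 n_i + 1) /
                     (max(m_L - s_L, 0)/2 + n_i + max(m_R - s_R, 0)/2 + 1))

  A uniform track scores exactly 0; a fully protected bond in an
  otherwise even landscape approaches 1.  Only positions whose flank
  has a median cleavage count above a threshold (default: strictly
  more than 15 reads per position over the 12 flanking nucleotides)
  are scored.

* **RT-stop fold change.**  Under limiting dNTPs the reverse
  transcriptase stalls one nucleotide downstream (3', transcript
  sense) of the methylated ribose, so the fraction of reads whose 5'
  end starts at ``i+1`` -- the RT-stop ratio ``r_i = S_{i+1}/C_{i+1}``
  -- is elevated in the low-dNTP library relative to the matched
  high-dNTP library from the same replicate.  The score is the fold
  change ``F_i = r_i(low) / r_i(high)``.

Sites are called by comparing per-replicate scores between knock-out
and parental samples with a two-sample, two-tailed pooled-variance
(Student's) t-test at every qualified position.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import Assay, Dntp, EndCountProfile, Genotype, LibraryMeta

logger = logging.getLogger(__name__)


class CountConvention(str, enum.Enum):
    """How cleavage events of bond i are tallied from read ends.

    A cleavage of the bond 3' of nucleotide ``i`` produces a fragment
    3' end at ``i`` and a fragment 5' end at ``i+1``; the default
    counts both witnesses.
    """

    ends_plus_nextstart = "ends_plus_nextstart"
    starts_only = "starts_only"
    ends_only = "ends_only"


@dataclass(frozen=True)
class CleavageParams:
    """Scoring parameters for the cleavage-protection assay.

    flank_len
        Number of bonds per side used for flank statistics (default 6,
        i.e. 12 flanking nucleotides total).
    min_median_reads
        Qualification threshold: the median cleavage count over the
        2*flank_len flanking bonds must strictly exceed this (default 15).
    convention
        Read-end bookkeeping for the cleavage count track.
    """

    flank_len: int = 6
    min_median_reads: float = 15.0
    convention: CountConvention = CountConvention.ends_plus_nextstart

    def __post_init__(self) -> None:
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")
        if self.min_median_reads < 0:
            raise ValueError("min_median_reads must be >= 0")


def cleavage_counts(
    profile: EndCountProfile,
    convention: CountConvention = CountConvention.ends_plus_nextstart,
) -> np.ndarray:
    """Per-bond cleavage counts ``n_i`` for bonds ``i = 1..L-1``.

    Bond ``i`` is the phosphodiester bond 3' of nucleotide ``i``
    (between nucleotides ``i`` and ``i+1``); element ``[i-1]`` of the
    returned array holds ``n_i``.
    """
    convention = CountConvention(convention)
    S, E = profile.starts5, profile.ends3
    if convention == CountConvention.ends_plus_nextstart:
        return E[:-1] + S[1:]
    if convention == CountConvention.starts_only:
        return S[1:].copy()
    return E[:-1].copy()


def _flank_windows(n: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Left and right flank matrices for interior bonds.

    For the ``(len(n) - 2w)`` bonds with a full flank, row ``k``
    corresponds to bond index ``k + w`` (0-based) and holds the ``w``
    counts on that side.
    """
    win = np.lib.stride_tricks.sliding_window_view(n, w)
    left = win[: len(n) - 2 * w]       # window starting at i - w
    right = win[w + 1:]                # window starting at i + 1
    return left, right


def qualify_positions(n: np.ndarray, params: CleavageParams) -> np.ndarray:
    """Boolean mask of bonds whose flank is deep enough to score.

    Bond ``i`` qualifies iff its full flank ``[i-w, i+w]`` (excluding
    ``i`` itself) lies within bounds and the median cleavage count over
    those ``2w`` bonds strictly exceeds ``min_median_reads``.  Edge
    bonds without a full flank never qualify.
    """
    n = np.asarray(n)
    w = params.flank_len
    B = len(n)
    mask = np.zeros(B, dtype=bool)
    if B < 2 * w + 1:
        return mask
    left, right = _flank_windows(n, w)
    flank = np.concatenate([left, right], axis=1)
    med = np.median(flank, axis=1)
    mask[w: B - w] = med > params.min_median_reads
    return mask


@dataclass
class ScoreTrack:
    """Cleavage-protection scores with qualification mask and audit stats.

    ``score[i-1]`` is ``A_i`` for qualified bonds and NaN elsewhere;
    flank means/SDs are retained for audit (NaN where undefined).
    """

    score: np.ndarray
    qualified: np.ndarray
    params: CleavageParams
    flank_mean_left: np.ndarray
    flank_sd_left: np.ndarray
    flank_mean_right: np.ndarray
    flank_sd_right: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(1, len(self.score) + 1),
            "score": self.score,
            "qualified": self.qualified,
        })


def score_a(n: np.ndarray, params: CleavageParams | None = None) -> ScoreTrack:
    """Cleavage-protection score A over all bonds of a cleavage track.

    Flank statistics use the population standard deviation; the flank
    means are shrunk by one SD (floored at zero) so that noisy flanks
    do not inflate protection, and the +1 pseudocounts keep the score
    defined at zero counts.  Scores are clamped to [0, 1]; unqualified
    bonds are NaN.
    """
    if params is None:
        params = CleavageParams()
    n = np.asarray(n, dtype=float)
    w = params.flank_len
    B = len(n)
    qualified = qualify_positions(n, params)

    mL = np.full(B, np.nan)
    sL = np.full(B, np.nan)
    mR = np.full(B, np.nan)
    sR = np.full(B, np.nan)
    score = np.full(B, np.nan)
    if B >= 2 * w + 1:
        left, right = _flank_windows(n, w)
        sl = slice(w, B - w)
        mL[sl] = left.mean(axis=1)
        sL[sl] = left.std(axis=1)  # population SD (ddof=0)
        mR[sl] = right.mean(axis=1)
        sR[sl] = right.std(axis=1)
        denom = (
            0.5 * np.maximum(mL[sl] - sL[sl], 0.0)
            + n[sl]
            + 0.5 * np.maximum(mR[sl] - sR[sl], 0.0)
            + 1.0
        )
        a = 1.0 - (2.0 * n[sl] + 1.0) / denom
        score[sl] = np.clip(a, 0.0, 1.0)
    score[~qualified] = np.nan
    return ScoreTrack(
        score=score, qualified=qualified, params=params,
        flank_mean_left=mL, flank_sd_left=sL,
        flank_mean_right=mR, flank_sd_right=sR,
    )


@dataclass
class RTStopTrack:
    """RT-stop ratios (and fold changes on comparison objects).

    ``ratio[i-1]`` is ``r_i = S_{i+1} / C_{i+1}`` (NaN where coverage
    at the stop position is zero); ``fold_change`` is filled only by
    :func:`rt_stop_fold_change`.
    """

    ratio: np.ndarray
    fold_change: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.ratio)


def rt_stop_ratio(profile: EndCountProfile) -> RTStopTrack:
    """Fraction of reads stopping one nucleotide downstream of each site.

    An RT stall at a methylated nucleotide ``i`` truncates the cDNA so
    the read's 5' end maps at ``i+1``; the ratio therefore divides the
    read-start count at the downstream position by the coverage there.
    """
    S, C = profile.starts5, profile.coverage
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(C[1:] > 0, S[1:] / C[1:], np.nan)
    return RTStopTrack(ratio=r)


def rt_stop_fold_change(low: RTStopTrack, high: RTStopTrack) -> RTStopTrack:
    """Low-dNTP stop ratio over matched high-dNTP (background) stop ratio.

    Positions where either ratio is undefined, or the high-dNTP ratio
    is zero, are excluded (NaN), never infinite.
    """
    if len(low) != len(high):
        raise ValueError(
            f"track lengths differ: {len(low)} vs {len(high)}"
        )
    rl, rh = low.ratio, high.ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(np.isfinite(rl) & np.isfinite(rh) & (rh > 0),
                     rl / rh, np.nan)
    return RTStopTrack(ratio=rl.copy(), fold_change=F)


@dataclass
class MethylationCall:
    """Replicate-level comparison of one position between two genotypes."""

    position: int
    method: str
    group_a_values: tuple[float, ...]
    group_b_values: tuple[float, ...]
    mean_a: float = math.nan
    mean_b: float = math.nan
    t_stat: float = math.nan
    p_value: float = math.nan
    significant: bool = False
    testable: bool = True
    degenerate: bool = False


def test_differential(
    group_a: Sequence[float],
    group_b: Sequence[float],
    position: int = 0,
    method: str = "cleavage",
    alpha: float = 0.05,
) -> MethylationCall:
    """Two-sample, two-tailed pooled-variance t-test on replicate scores.

    Scores enter untransformed.  NaN replicates are dropped; fewer
    than two defined values in either group marks the position
    untestable rather than raising.  A degenerate zero-pooled-variance
    comparison yields p = 1 for equal means, otherwise the position is
    flagged degenerate with p reported as 0 and a warning.
    """
    a = np.asarray([v for v in group_a if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in group_b if np.isfinite(v)], dtype=float)
    call = MethylationCall(
        position=position, method=method,
        group_a_values=tuple(a), group_b_values=tuple(b),
    )
    if len(a) < 2 or len(b) < 2:
        call.testable = False
        return call
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    call.mean_a, call.mean_b = float(ma), float(mb)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if ma == mb:
            call.t_stat, call.p_value = 0.0, 1.0
        else:
            logger.warning(
                "position %d: zero pooled variance with unequal means; "
                "flagging degenerate-significant", position,
            )
            call.degenerate = True
            call.t_stat = math.inf if ma > mb else -math.inf
            call.p_value = 0.0
            call.significant = True
        return call
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    call.t_stat, call.p_value = float(t), float(min(p, 1.0))
    call.significant = call.p_value < alpha
    return call


# ---------------------------------------------------------------------------
# transcriptome scan


def _score_matrix_cleavage(
    profiles: Sequence[EndCountProfile], params: CleavageParams,
) -> np.ndarray:
    """Rows: replicates; columns: bonds; NaN where unqualified."""
    rows = []
    for p in profiles:
        n = cleavage_counts(p, params.convention)
        rows.append(score_a(n, params).score)
    return np.vstack(rows)


def _score_matrix_rtstop(
    pairs: Sequence[tuple[EndCountProfile, EndCountProfile]],
) -> np.ndarray:
    rows = []
    for low, high in pairs:
        fc = rt_stop_fold_change(rt_stop_ratio(low), rt_stop_ratio(high))
        rows.append(fc.fold_change)
    return np.vstack(rows)


def _group_rtstop_pairs(
    profiles: Sequence[EndCountProfile], genotype: Genotype,
) -> list[tuple[EndCountProfile, EndCountProfile]]:
    by_rep: dict[int, dict[Dntp, EndCountProfile]] = {}
    for p in profiles:
        m = p.meta
        if m.assay == Assay.rtstop and m.genotype == genotype:
            by_rep.setdefault(m.replicate, {})[m.dntp] = p
    pairs = []
    for rep, d in sorted(by_rep.items()):
        if Dntp.low not in d or Dntp.high not in d:
            present = d[Dntp.low] if Dntp.low in d else d[Dntp.high]
            raise ValueError(
                f"rtstop replicate {rep} of genotype {genotype.value} lacks "
                f"its dNTP partner (have sample {present.meta.sample_id})"
            )
        pairs.append((d[Dntp.low], d[Dntp.high]))
    return pairs


def scan_transcriptome(
    profiles: Iterable[EndCountProfile],
    params: CleavageParams | None = None,
    alpha: float = 0.05,
    add_bh: bool = True,
) -> pd.DataFrame:
    """Call differential methylation between knock-out and parental samples.

    For every non-parental genotype present, and for each assay method
    available (cleavage protection and/or RT-stop fold change), a
    pooled-variance t-test compares per-replicate scores against the
    parental group at every position with at least two defined values
    per group.  Raw p-values are primary; a Benjamini-Hochberg q-value
    column is appended (per genotype and method) unless ``add_bh`` is
    False, without altering the primary calls.

    Returns a position-sorted DataFrame with columns position, method,
    genotype, mean_ko, mean_parental, t, p, q, significant, degenerate.
    """
    if params is None:
        params = CleavageParams()
    profiles = list(profiles)
    rows: list[dict] = []

    genotypes = sorted(
        {p.meta.genotype for p in profiles} - {Genotype.parental},
        key=lambda g: g.value,
    )
    for genotype in genotypes:
        for method in ("cleavage", "rtstop"):
            if method == "cleavage":
                ko = [p for p in profiles
                      if p.meta.assay == Assay.cleavage
                      and p.meta.genotype == genotype]
                par = [p for p in profiles
                       if p.meta.assay == Assay.cleavage
                       and p.meta.genotype == Genotype.parental]
                if not ko or not par:
                    continue
                mat_ko = _score_matrix_cleavage(ko, params)
                mat_par = _score_matrix_cleavage(par, params)
            else:
                ko_pairs = _group_rtstop_pairs(profiles, genotype)
                par_pairs = _group_rtstop_pairs(profiles, Genotype.parental)
                if not ko_pairs or not par_pairs:
                    continue
                mat_ko = _score_matrix_rtstop(ko_pairs)
                mat_par = _score_matrix_rtstop(par_pairs)
            if mat_ko.shape[1] != mat_par.shape[1]:
                raise ValueError("knock-out and parental profiles have "
                                 "different reference lengths")
            testable = (
                (np.isfinite(mat_ko).sum(axis=0) >= 2)
                & (np.isfinite(mat_par).sum(axis=0) >= 2)
            )
            for idx in np.nonzero(testable)[0]:
                call = test_differential(
                    mat_ko[:, idx], mat_par[:, idx],
                    position=int(idx) + 1, method=method, alpha=alpha,
                )
                rows.append({
                    "position": call.position,
                    "method": method,
                    "genotype": genotype.value,
                    "mean_ko": call.mean_a,
                    "mean_parental": call.mean_b,
                    "t": call.t_stat,
                    "p": call.p_value,
                    "significant": call.significant,
                    "degenerate": call.degenerate,
                })

    columns = ["position", "method", "genotype", "mean_ko", "mean_parental",
               "t", "p", "significant", "degenerate"]
    table = pd.DataFrame(rows, columns=columns)
    if add_bh:
        table["q"] = np.nan
        if len(table):
            from statsmodels.stats.multitest import multipletests

            for (_, _), idx in table.groupby(["genotype", "method"]).groups.items():
                pvals = table.loc[idx, "p"].to_numpy()
                table.loc[idx, "q"] = multipletests(pvals, method="fdr_bh")[1]
    return table.sort_values(["genotype", "method", "position"]).reset_index(
        drop=True
    )
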