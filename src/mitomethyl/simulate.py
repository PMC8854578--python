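"""Seeded generators emulating both assays, footprint libraries and SILAC.

Every generator is a pure function of (parameters, truth, seed) and
carries its ground truth explicitly, so each pipeline stage can be
tested for recovery of planted signal without external data.

Cleavage libraries emulate alkaline fragmentation: each phosphodiester
bond receives a mean-1 gamma cleavage propensity (sequence-dependent
heterogeneity), scaled down by ``1 - protection`` at 2'-O-methylated
bonds; fragments are pairs of cut points accepted when their length
falls in the library's size-selection window.

RT-stop libraries superimpose reverse-transcription truncation on
random fragments: the enzyme walks 3'->5' from the fragment end with a
per-nucleotide background drop-off and an extra stall probability when
the next template nucleotide is 2'-O-methylated, producing a read 5'
start one nucleotide downstream of the site.  Both signal sources
(fragment ends and stall starts) therefore coexist in the profile, as
in real libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .occupancy import (
    DEFAULT_START_WINDOW,
    DEFAULT_STOP_WINDOW,
    FootprintRead,
    MtAnnotation,
)
from .profiles import (
    Assay,
    Dntp,
    EndCountProfile,
    Genotype,
    LibraryMeta,
    ReferenceIndex,
    Strand,
)

logger = logging.getLogger(__name__)

import pandas as pd


@dataclass(frozen=True)
class MethylSite:
    """One planted 2'-O-methylated residue and its assay parameters.

    ``protection`` is the fractional resistance of the bond 3' of the
    site to alkaline hydrolysis; ``q_low``/``q_high`` are the RT stall
    probabilities under limiting/saturating dNTPs.
    """

    position: int
    protection: float = 0.0
    q_low: float = 0.0
    q_high: float = 0.0

    def __post_init__(self) -> None:
        for name in ("protection", "q_low", "q_high"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimulationTruth:
    """Planted ground truth shared by all generators."""

    sites: tuple[MethylSite, ...] = ()
    occupancy_factors: dict[str, float] = field(default_factory=dict)
    mixing_bias: float = 1.0
    subunit_effect_log2: float = 0.0

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        for s in self.sites:
            if s.q_low < s.q_high:
                logger.warning(
                    "site %d has q_low (%.3f) < q_high (%.3f); the assay "
                    "expects stronger stalling under limiting dNTPs",
                    s.position, s.q_low, s.q_high,
                )
        if self.mixing_bias <= 0:
            raise ValueError("mixing_bias must be positive")

    def to_yaml(self, path) -> None:
        doc = {
            "sites": [
                {"position": s.position, "protection": s.protection,
                 "q_low": s.q_low, "q_high": s.q_high}
                for s in self.sites
            ],
            "occupancy_factors": dict(self.occupancy_factors),
            "mixing_bias": self.mixing_bias,
            "subunit_effect_log2": self.subunit_effect_log2,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            sites=tuple(MethylSite(**s) for s in doc.get("sites", [])),
            occupancy_factors=doc.get("occupancy_factors", {}) or {},
            mixing_bias=doc.get("mixing_bias", 1.0),
            subunit_effect_log2=doc.get("subunit_effect_log2", 0.0),
        )


# ---------------------------------------------------------------------------
# alkaline-fragmentation (cleavage-protection) libraries


@dataclass(frozen=True)
class CleavageSimParams:
    """Parameters of one alkaline-fragmentation library simulation.

    ``dispersion`` is the variance of the mean-1 gamma distribution of
    per-bond cleavage propensities (0 gives a uniform landscape);
    ``frag_len`` is the sequenced size-selection window in nt.
    """

    length: int = 2000
    n_frag: int = 20000
    dispersion: float = 0.3
    frag_len: tuple[int, int] = (25, 55)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("reference length must be >= 2")
        if self.n_frag <= 0:
            raise ValueError("n_frag must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.frag_len
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid fragment length range {self.frag_len}")


def draw_bond_weights(
    length: int, dispersion: float, rng: np.random.Generator,
) -> np.ndarray:
    """Mean-1 gamma cleavage propensities for cut points 0..L.

    Cut points 0 and L are the molecule termini and keep weight 1;
    internal cut point ``i`` is the bond 3' of nucleotide ``i``.
    """
    w = np.ones(length + 1)
    if dispersion > 0:
        shape = 1.0 / dispersion
        w[1:length] = rng.gamma(shape, scale=dispersion, size=length - 1)
    return w


def _apply_protection(weights: np.ndarray, truth: SimulationTruth) -> np.ndarray:
    w = weights.copy()
    L = len(w) - 1
    for site in truth.sites:
        if not (1 <= site.position <= L - 1):
            raise ValueError(
                f"methylated site {site.position} outside bond range "
                f"[1, {L - 1}]"
            )
        w[site.position] *= 1.0 - site.protection
    return w


def _sample_fragments(
    weights: np.ndarray, n_frag: int, frag_len: tuple[int, int],
    rng: np.random.Generator, max_attempt_factor: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of cut points drawn from the weight distribution.

    Both cut points are drawn independently with probability
    proportional to the cleavage weights; a pair (a, b) is accepted
    when the fragment [a+1, b] has length b - a inside ``frag_len``.
    """
    L = len(weights) - 1
    probs = weights / weights.sum()
    lo, hi = frag_len
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    accepted = 0
    drawn = 0
    budget = max_attempt_factor * n_frag
    while accepted < n_frag:
        batch = min(max(4 * (n_frag - accepted) * max(L // max(hi - lo, 1), 1),
                        10000), 2_000_000)
        if drawn + batch > budget:
            batch = budget - drawn
            if batch <= 0:
                raise ValueError(
                    "fragment acceptance rate too low; widen frag_len or "
                    "check the protection/weight configuration"
                )
        a = rng.choice(L + 1, size=batch, p=probs)
        b = rng.choice(L + 1, size=batch, p=probs)
        drawn += batch
        d = b - a
        ok = (d >= lo) & (d <= hi)
        take = min(int(ok.sum()), n_frag - accepted)
        idx = np.nonzero(ok)[0][:take]
        starts.append(a[idx] + 1)
        ends.append(b[idx])
        accepted += take
    return np.concatenate(starts), np.concatenate(ends)


def simulate_cleavage_profiles(
    params: CleavageSimParams,
    truth: SimulationTruth,
    genotype: Genotype = Genotype.parental,
    reference_name: str = "chrM",
    bond_weights: np.ndarray | None = None,
) -> list[EndCountProfile]:
    """Replicate alkaline-fragmentation profiles with planted protection.

    The per-bond heterogeneity landscape is drawn once from a dedicated
    substream of the seed and shared across replicates (it models
    sequence-dependent hydrolysis, a property of the reference);
    ``bond_weights`` may be supplied explicitly so that contrasting
    genotypes simulated in separate calls share the same landscape.
    Deterministic given (params, truth, genotype, weights).
    """
    L = params.length
    master = np.random.SeedSequence(params.seed)
    weight_ss, *rep_ss = master.spawn(params.replicates + 1)
    if bond_weights is None:
        bond_weights = draw_bond_weights(
            L, params.dispersion, np.random.default_rng(weight_ss)
        )
    if len(bond_weights) != L + 1:
        raise ValueError(
            f"bond_weights must have length L+1 = {L + 1}, got "
            f"{len(bond_weights)}"
        )
    weights = _apply_protection(bond_weights, truth)
    reference = ReferenceIndex(name=reference_name, length_nt=L)
    profiles = []
    for r, ss in enumerate(rep_ss, start=1):
        rng = np.random.default_rng(ss)
        s, e = _sample_fragments(weights, params.n_frag, params.frag_len, rng)
        meta = LibraryMeta(
            sample_id=f"{genotype.value}_cleavage_rep{r}",
            genotype=genotype, assay=Assay.cleavage,
            dntp=Dntp.not_applicable, replicate=r,
        )
        profiles.append(EndCountProfile.from_intervals(
            zip(s.tolist(), e.tolist()), reference, Strand.plus, meta,
        ))
    return profiles


# ---------------------------------------------------------------------------
# RT-stop libraries


@dataclass(frozen=True)
class RtStopSimParams:
    """Parameters of one RT-stop library simulation.

    ``dropoff`` is the per-nucleotide background truncation probability
    of the reverse transcriptase; fragments (the RNA templates) are
    uniform random spans within the size-selection window.
    """

    length: int = 2000
    n_frag: int = 20000
    dropoff: float = 0.001
    frag_len: tuple[int, int] = (25, 55)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("reference length must be >= 2")
        if self.n_frag <= 0:
            raise ValueError("n_frag must be positive")
        if not (0.0 <= self.dropoff < 1.0):
            raise ValueError("dropoff must be in [0, 1)")
        lo, hi = self.frag_len
        if not (1 <= lo <= hi <= self.length):
            raise ValueError(f"invalid fragment length range {self.frag_len}")


def _uniform_fragments(
    L: int, n: int, frag_len: tuple[int, int], rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragments uniform over all valid (start, length) combinations."""
    lo, hi = frag_len
    s = np.empty(n, dtype=np.int64)
    e = np.empty(n, dtype=np.int64)
    have = 0
    while have < n:
        batch = max(2 * (n - have), 1000)
        cs = rng.integers(1, L + 1, size=batch)
        cl = rng.integers(lo, hi + 1, size=batch)
        ce = cs + cl - 1
        ok = ce <= L
        take = min(int(ok.sum()), n - have)
        idx = np.nonzero(ok)[0][:take]
        s[have:have + take] = cs[idx]
        e[have:have + take] = ce[idx]
        have += take
    return s, e


def simulate_rtstop_profiles(
    params: RtStopSimParams,
    truth: SimulationTruth,
    condition: Dntp,
    genotype: Genotype = Genotype.parental,
    replicate: int = 1,
    reference_name: str = "chrM",
) -> EndCountProfile:
    """One RT-stop library under the given dNTP condition.

    Each template fragment is reverse transcribed 3'->5'; at every
    extension step the enzyme falls off with probability ``dropoff``,
    and additionally stalls with probability ``q_low``/``q_high`` when
    the next template position is a planted site, leaving a read that
    starts one nucleotide downstream (3') of the site.  The emitted
    profile satisfies the coverage identity by construction.
    Deterministic given (params, truth, condition, genotype, replicate).
    """
    condition = Dntp(condition)
    if condition not in (Dntp.low, Dntp.high):
        raise ValueError("condition must be low or high")
    L = params.length
    ss = np.random.SeedSequence(
        [params.seed, replicate, 0 if condition == Dntp.low else 1]
    )
    rng = np.random.default_rng(ss)
    s, e = _uniform_fragments(L, params.n_frag, params.frag_len, rng)

    # background drop-off: number of successful extension steps before
    # the first failure is geometric
    if params.dropoff > 0:
        K = rng.geometric(params.dropoff, size=params.n_frag) - 1
        start = np.maximum(s, e - K)
    else:
        start = s.copy()
    for site in truth.sites:
        i = site.position
        if not (1 <= i <= L - 1):
            raise ValueError(f"site {i} outside [1, {L - 1}]")
        q = site.q_low if condition == Dntp.low else site.q_high
        if q <= 0:
            continue
        eligible = (s <= i) & (i <= e - 1)
        stalled = eligible & (rng.random(params.n_frag) < q)
        start = np.where(stalled, np.maximum(start, i + 1), start)

    reference = ReferenceIndex(name=reference_name, length_nt=L)
    meta = LibraryMeta(
        sample_id=f"{genotype.value}_rtstop_{condition.value}_rep{replicate}",
        genotype=genotype, assay=Assay.rtstop, dntp=condition,
        replicate=replicate,
    )
    return EndCountProfile.from_intervals(
        zip(start.tolist(), e.tolist()), reference, Strand.plus, meta,
    )


# ---------------------------------------------------------------------------
# mitoribosome footprint libraries


@dataclass(frozen=True)
class FootprintSimParams:
    """Parameters of one footprint library simulation.

    ``scale`` is the expected footprint count per CDS nucleotide at
    occupancy factor 1; ``nuclear_normaliser`` is the library's
    positive-sense nuclear-mRNA read count used for RPM.
    """

    annotation: MtAnnotation
    scale: float = 1.0
    nuclear_normaliser: int = 2_000_000
    footprint_len: tuple[int, int] = (25, 35)
    start_window: int = DEFAULT_START_WINDOW
    stop_window: int = DEFAULT_STOP_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.nuclear_normaliser <= 0:
            raise ValueError("nuclear_normaliser must be positive")
        lo, hi = self.footprint_len
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid footprint length range "
                             f"{self.footprint_len}")


def _allowed_positions(
    gene, annotation: MtAnnotation, start_window: int, stop_window: int,
) -> np.ndarray:
    """Reference positions whose footprints survive all filtering rules."""
    offsets = np.arange(start_window, gene.cds_length - stop_window)
    if offsets.size == 0:
        return offsets
    if gene.strand == Strand.plus:
        pos = gene.cds_start + offsets
    else:
        pos = gene.cds_end - offsets
    keep = np.ones(len(pos), dtype=bool)
    for ov in annotation.overlaps:
        keep &= ~((pos >= ov.start) & (pos <= ov.end))
    return pos[keep]


def simulate_footprint_library(
    params: FootprintSimParams, truth: SimulationTruth,
) -> tuple[list[FootprintRead], int]:
    """Footprint reads for every annotated mt-mRNA plus the normaliser count.

    Per gene, the read count is Poisson with mean CDS length x occupancy
    factor x scale; 5' positions are uniform over the CDS offsets that
    survive the initiation/termination windows and overlap exclusion, so
    planted occupancy factors propagate directly to filtered counts.
    Deterministic given (params, truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    reads: list[FootprintRead] = []
    lo, hi = params.footprint_len
    for gene in params.annotation.mrna_genes():
        factor = truth.occupancy_factors.get(gene.gene, 1.0)
        if factor < 0:
            raise ValueError(f"occupancy factor for {gene.gene} must be >= 0")
        mean = gene.cds_length * factor * params.scale
        count = int(rng.poisson(mean)) if mean > 0 else 0
        if count == 0:
            continue
        allowed = _allowed_positions(
            gene, params.annotation, params.start_window, params.stop_window
        )
        if allowed.size == 0:
            logger.warning("gene %s has no allowed footprint positions",
                           gene.gene)
            continue
        pos = rng.choice(allowed, size=count)
        lens = rng.integers(lo, hi + 1, size=count)
        reads.extend(
            FootprintRead(five_prime_pos=int(p), length=int(l),
                          strand=gene.strand)
            for p, l in zip(pos, lens)
        )
    return reads, params.nuclear_normaliser


# ---------------------------------------------------------------------------
# SILAC ratio tables


def simulate_silac_table(
    truth: SimulationTruth,
    n_per_subunit: int = 30,
    n_whole_cell: int = 200,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """SILAC heavy/light ratio table with a global mixing bias.

    mtLSU proteins carry the planted subunit effect (log2); mtSSU and
    background proteins carry none.  Both label orientations are
    emitted, the swapped orientation with the effect sign reversed, and
    every ratio is multiplied by the mixing bias.  Also returns the
    median ratio of a simulated whole-cell lysate mix (effect-free
    proteins), the input to :func:`mitomethyl.ancillary.correct_mixing`.
    Deterministic given (truth, sizes, noise_sd, seed).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    e = truth.subunit_effect_log2
    log2b = np.log2(truth.mixing_bias)
    rows = []
    for subunit, effect in (("mtSSU", 0.0), ("mtLSU", e), ("other", 0.0)):
        for k in range(n_per_subunit):
            protein = f"{subunit}_{k + 1:03d}"
            for orientation, sign in (("forward", 1.0), ("swapped", -1.0)):
                log2r = (sign * effect + log2b
                         + rng.normal(0.0, noise_sd))
                rows.append({
                    "protein": protein, "subunit": subunit, "fraction": 1,
                    "ratio": float(2.0 ** log2r),
                    "orientation": orientation,
                })
    table = pd.DataFrame(rows, columns=["protein", "subunit", "fraction",
                                        "ratio", "orientation"])
    whole = 2.0 ** (log2b + rng.normal(0.0, noise_sd, size=n_whole_cell))
    return table, float(np.median(whole))
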