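"""Forward simulation of case-parent trios in a candidate region.

The population model mirrors the classic founder-haplotype setting used to
benchmark family-based candidate-region tests: q biallelic markers evenly
spaced across a region (default 20 markers / 100 kb), background haplotypes
generated marker-by-marker with a first-order Markov chain whose adjacent-
pair linkage disequilibrium is drawn as a standardized coefficient D' and
converted to a raw covariance D through the Lewontin bound, and a single
latent disease allele D (population frequency 0.1) introduced a fixed number
of generations ago on one "ancestral" haplotype.  Each generation a
D-bearing haplotype may recombine against a random background haplotype, so
marker-disease LD decays with the age of the mutation.

Trios are formed by drawing two parental diplotypes from the haplotype pool,
transmitting one (possibly recombined) gamete from each parent, and keeping
the trio if the child is affected.  The affection probability is
``baseline * f(g)`` where f is the relative-risk factor (1, R1, R2 for
0/1/2 copies of D) of the child's genotype (child effect), the mother's
genotype (maternal effect), or the product of both factors (joint effect).
The disease locus itself is latent: only the marker genotypes are reported,
as counts of each marker's "A" allele.

An admixed population draws each trio's parents from one of two
subpopulations (no intermarriage by default) that differ in disease-allele
frequency, baseline risk, mutation age, ancestral haplotype, marker
frequencies and LD — the stratification setting trio designs must tolerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trio_stats import MISSING, TrioGenotypes

__all__ = [
    "PopulationModel",
    "AdmixtureModel",
    "DiseaseScenario",
    "RealizedPopulation",
    "dprime_to_d",
    "build_marker_haplotypes",
    "evolve_disease_haplotypes",
    "realize_population",
    "sample_affected_trios",
    "mask_genotypes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PopulationModel:
    """Candidate-region population parameters for one (sub)population.

    Defaults give the standard benchmark setting: 20 markers over 100 kb,
    allele-"A" frequencies uniform on (0.1, 0.9), adjacent-pair D' uniform
    on (-0.9, 0.9), disease allele at frequency 0.1 introduced 1,000
    generations ago, and a 1 cM/Mb recombination map (so the whole region
    spans 0.1 cM, i.e. crossover probability 0.001 per meiosis).
    """

    n_markers: int = 20
    region_bp: float = 100_000.0
    disease_freq: float = 0.1
    generations: int = 1000
    recomb_prob: float = 1e-3       # P(crossover in region per meiosis)
    pool_size: int = 10_000
    freq_range: tuple[float, float] = (0.1, 0.9)
    dprime_range: tuple[float, float] = (-0.9, 0.9)

    def __post_init__(self):
        if self.n_markers < 1 or self.pool_size < 2:
            raise ValueError("need at least one marker and two haplotypes")
        if not 0.0 < self.disease_freq < 1.0:
            raise ValueError("disease_freq must be in (0, 1)")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ValueError("recomb_prob must be a probability")

    @property
    def positions(self) -> np.ndarray:
        """Marker positions (bp), evenly spaced in the interior of the region."""
        q = self.n_markers
        return self.region_bp * (np.arange(1, q + 1)) / (q + 1)


@dataclass(frozen=True)
class AdmixtureModel:
    """Two subpopulations admixing at the study generation.

    Both parents of any trio come from the same subpopulation, drawn with
    the mixing proportions; ``baselines`` optionally overrides the
    scenario's baseline risk per subpopulation.
    """

    pop1: PopulationModel
    pop2: PopulationModel
    mixing: tuple[float, float] = (0.3, 0.7)
    baselines: tuple[float, float] | None = None

    def __post_init__(self):
        if abs(sum(self.mixing) - 1.0) > 1e-9 or min(self.mixing) < 0:
            raise ValueError("mixing proportions must be nonnegative and sum to 1")

    @classmethod
    def default(cls) -> "AdmixtureModel":
        """The benchmark admixture scenario: D at frequency 0.1 vs 0.2,
        introduced 1,000 vs 500 generations ago, baseline risk 0.01 vs
        0.05, mixed 30/70."""
        return cls(
            pop1=PopulationModel(disease_freq=0.1, generations=1000),
            pop2=PopulationModel(disease_freq=0.2, generations=500),
            mixing=(0.3, 0.7),
            baselines=(0.01, 0.05),
        )


@dataclass(frozen=True)
class DiseaseScenario:
    """Penetrance model: P(affected) = baseline * relative-risk factor(s).

    ``effect`` selects whose genotype carries the risk: the child's
    ("child", association), the mother's ("maternal", maternally mediated
    effect), or both multiplicatively ("joint").
    """

    baseline: float = 0.01
    r1: float = 2.0
    r2: float = 2.0
    effect: str = "child"

    def __post_init__(self):
        if not 0.0 < self.baseline < 1.0:
            raise ValueError("baseline must be in (0, 1)")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("relative risks must be nonnegative")
        if self.effect not in ("child", "maternal", "joint"):
            raise ValueError("effect must be 'child', 'maternal' or 'joint'")
        if self.max_penetrance(self.baseline) > 1.0:
            raise ValueError("penetrance exceeds 1 under this scenario")

    @classmethod
    def null(cls, baseline: float = 0.01) -> "DiseaseScenario":
        """No association and no maternal effect (R1 = R2 = 1)."""
        return cls(baseline=baseline, r1=1.0, r2=1.0, effect="child")

    @property
    def is_null(self) -> bool:
        return self.r1 == 1.0 and self.r2 == 1.0

    def risk_factor(self, g: np.ndarray) -> np.ndarray:
        """Relative-risk factor for 0/1/2 copies of the disease allele."""
        table = np.array([1.0, self.r1, self.r2])
        return table[np.asarray(g, dtype=np.int64)]

    def max_penetrance(self, baseline: float) -> float:
        m = max(1.0, self.r1, self.r2)
        return baseline * (m * m if self.effect == "joint" else m)

    def penetrance(self, child_d: np.ndarray, mother_d: np.ndarray,
                   baseline: float | None = None) -> np.ndarray:
        b = self.baseline if baseline is None else baseline
        if self.effect == "child":
            return b * self.risk_factor(child_d)
        if self.effect == "maternal":
            return b * self.risk_factor(mother_d)
        return b * self.risk_factor(child_d) * self.risk_factor(mother_d)


# ---------------------------------------------------------------------------
# Haplotype generation
# ---------------------------------------------------------------------------

def dprime_to_d(p1, p2, dprime):
    """Convert standardized D' to raw D for allele frequencies p1, p2.

    Uses the Lewontin maximum: for D' >= 0, Dmax = min(p1(1-p2), (1-p1)p2);
    for D' < 0, Dmax = min(p1 p2, (1-p1)(1-p2)).  Guarantees the implied
    conditional probabilities are valid for every frequency pair.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    dprime = np.asarray(dprime, dtype=np.float64)
    dmax_pos = np.minimum(p1 * (1 - p2), (1 - p1) * p2)
    dmax_neg = np.minimum(p1 * p2, (1 - p1) * (1 - p2))
    return dprime * np.where(dprime >= 0, dmax_pos, dmax_neg)


def build_marker_haplotypes(freqs, adj_d, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample n marker haplotypes from the first-order Markov chain.

    ``freqs[l]`` is the frequency of allele "A" at marker l and ``adj_d[l]``
    the raw disequilibrium between markers l and l+1, so
    P(A at l+1 | A at l) = p_{l+1} + D/p_l and
    P(A at l+1 | a at l) = p_{l+1} - D/(1-p_l).
    Returns an (n, q) 0/1 matrix (1 = allele "A").
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    adj_d = np.asarray(adj_d, dtype=np.float64)
    q = freqs.size
    if adj_d.size != max(q - 1, 0):
        raise ValueError("adj_d must have length n_markers - 1")
    haps = np.empty((n, q), dtype=np.int8)
    haps[:, 0] = rng.random(n) < freqs[0]
    for l in range(q - 1):
        p_given_a = np.clip(freqs[l + 1] + adj_d[l] / freqs[l], 0.0, 1.0)
        p_given_b = np.clip(freqs[l + 1] - adj_d[l] / (1.0 - freqs[l]), 0.0, 1.0)
        prob = np.where(haps[:, l] == 1, p_given_a, p_given_b)
        haps[:, l + 1] = rng.random(n) < prob
    return haps


def evolve_disease_haplotypes(ancestral: np.ndarray, n: int,
                              model: PopulationModel,
                              freqs, adj_d, disease_pos: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Descend n copies of the ancestral D-haplotype through G generations.

    Each generation a lineage recombines against a fresh background
    haplotype with probability ``model.recomb_prob`` (at most one crossover
    per meiosis, breakpoint uniform on the region).  The D-carrying product
    keeps the side of the breakpoint containing the disease locus, so the
    number of crossover events per lineage is Binomial(G, r) and events are
    applied sequentially (later events overwrite earlier background
    segments on the same side).
    """
    if model.generations < 0:
        raise ValueError("generations must be >= 0")
    positions = model.positions
    haps = np.tile(np.asarray(ancestral, dtype=np.int8), (n, 1))
    k = rng.binomial(model.generations, model.recomb_prob, size=n)
    for round_ in range(int(k.max()) if n else 0):
        active = np.nonzero(k > round_)[0]
        m = active.size
        bp = rng.uniform(0.0, model.region_bp, m)
        background = build_marker_haplotypes(freqs, adj_d, m, rng)
        left = positions[None, :] < bp[:, None]
        # breakpoint left of the disease locus -> background on the left,
        # otherwise background on the right
        from_background = np.where((bp < disease_pos)[:, None], left, ~left)
        sub = haps[active]
        sub[from_background] = background[from_background]
        haps[active] = sub
    return haps


@dataclass(frozen=True)
class RealizedPopulation:
    """One concrete draw of a population: frequencies, LD, and the pool."""

    model: PopulationModel
    marker_freqs: np.ndarray
    adj_dprime: np.ndarray
    adj_d: np.ndarray
    disease_pos: float
    ancestral: np.ndarray
    hap_markers: np.ndarray        # (pool_size, q) 0/1
    hap_d: np.ndarray              # (pool_size,) 0/1

    @property
    def positions(self) -> np.ndarray:
        return self.model.positions


def realize_population(model: PopulationModel,
                       rng: np.random.Generator) -> RealizedPopulation:
    """Draw frequencies, LD, the disease locus and the haplotype pool."""
    q = model.n_markers
    freqs = rng.uniform(*model.freq_range, q)
    dprime = rng.uniform(*model.dprime_range, max(q - 1, 0))
    adj_d = dprime_to_d(freqs[:-1], freqs[1:], dprime) if q > 1 else np.empty(0)
    disease_pos = rng.uniform(0.0, model.region_bp)
    ancestral = build_marker_haplotypes(freqs, adj_d, 1, rng)[0]
    n_d = int(round(model.pool_size * model.disease_freq))
    n_d = min(max(n_d, 1), model.pool_size - 1)
    d_haps = evolve_disease_haplotypes(ancestral, n_d, model, freqs, adj_d,
                                       disease_pos, rng)
    bg = build_marker_haplotypes(freqs, adj_d, model.pool_size - n_d, rng)
    markers = np.concatenate([d_haps, bg], axis=0)
    hap_d = np.zeros(model.pool_size, dtype=np.int8)
    hap_d[:n_d] = 1
    return RealizedPopulation(model=model, marker_freqs=freqs,
                              adj_dprime=dprime, adj_d=adj_d,
                              disease_pos=float(disease_pos),
                              ancestral=ancestral, hap_markers=markers,
                              hap_d=hap_d)


# ---------------------------------------------------------------------------
# Trio sampling
# ---------------------------------------------------------------------------

def _transmit(h1, h2, d1, d2, pop: RealizedPopulation,
              rng: np.random.Generator):
    """One gamete per parent from diplotype (h1, h2) with a fresh meiosis."""
    m = h1.shape[0]
    positions = pop.positions
    pick_first = rng.random(m) < 0.5
    ha = np.where(pick_first[:, None], h1, h2)
    hb = np.where(pick_first[:, None], h2, h1)
    da = np.where(pick_first, d1, d2)
    db = np.where(pick_first, d2, d1)
    rec = rng.random(m) < pop.model.recomb_prob
    bp = rng.uniform(0.0, pop.model.region_bp, m)
    seg_a = positions[None, :] < bp[:, None]      # left of breakpoint <- ha
    gam = np.where(rec[:, None], np.where(seg_a, ha, hb), ha)
    gd = np.where(rec, np.where(pop.disease_pos < bp, da, db), da)
    return gam, gd


def _candidate_trios(pop: RealizedPopulation, m: int,
                     rng: np.random.Generator):
    """m random mating candidates: genotype counts + parental/child D dosage."""
    idx = rng.integers(0, pop.hap_markers.shape[0], size=(4, m))
    mh1, mh2 = pop.hap_markers[idx[0]], pop.hap_markers[idx[1]]
    fh1, fh2 = pop.hap_markers[idx[2]], pop.hap_markers[idx[3]]
    md1, md2 = pop.hap_d[idx[0]], pop.hap_d[idx[1]]
    fd1, fd2 = pop.hap_d[idx[2]], pop.hap_d[idx[3]]
    gm, gm_d = _transmit(mh1, mh2, md1, md2, pop, rng)
    gf, gf_d = _transmit(fh1, fh2, fd1, fd2, pop, rng)
    M = (mh1 + mh2).astype(np.int64)
    F = (fh1 + fh2).astype(np.int64)
    C = (gm + gf).astype(np.int64)
    mother_d = (md1 + md2).astype(np.int64)
    child_d = (gm_d + gf_d).astype(np.int64)
    return M, F, C, child_d, mother_d


def sample_affected_trios(model: PopulationModel | AdmixtureModel,
                          scenario: DiseaseScenario, n_trios: int,
                          rng: np.random.Generator) -> TrioGenotypes:
    """Ascertain n_trios case-parent trios under the given disease scenario.

    Candidates are mating draws from the haplotype pool(s); each is kept
    with probability proportional to its affection probability (rejection
    sampling against the scenario's maximum penetrance, which leaves the
    conditional distribution of ascertained trios unchanged).  The
    population (frequencies, LD, disease position, ancestral haplotype,
    pool) is redrawn on every call.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    if isinstance(model, AdmixtureModel):
        pops = [realize_population(model.pop1, rng),
                realize_population(model.pop2, rng)]
        baselines = (model.baselines if model.baselines is not None
                     else (scenario.baseline, scenario.baseline))
        mixing = np.asarray(model.mixing)
    else:
        pops = [realize_population(model, rng)]
        baselines = (scenario.baseline,)
        mixing = np.asarray([1.0])
    p_max = max(scenario.max_penetrance(b) for b in baselines)
    if p_max > 1.0:
        raise ValueError("penetrance exceeds 1 under this scenario")

    parts_M, parts_F, parts_C = [], [], []
    collected, total_drawn, accept_est = 0, 0, 0.5
    while collected < n_trios:
        batch = int(min(max(256, 1.5 * (n_trios - collected) / accept_est),
                        200_000))
        counts = rng.multinomial(batch, mixing)
        for pop, base, mk in zip(pops, baselines, counts):
            mk = int(mk)
            if mk == 0:
                continue
            M, F, C, child_d, mother_d = _candidate_trios(pop, mk, rng)
            pen = scenario.penetrance(child_d, mother_d, baseline=base)
            keep = rng.random(mk) < pen / p_max
            parts_M.append(M[keep])
            parts_F.append(F[keep])
            parts_C.append(C[keep])
            collected += int(keep.sum())
        total_drawn += batch
        accept_est = max(collected / total_drawn, 0.005)
    M = np.concatenate(parts_M)[:n_trios]
    F = np.concatenate(parts_F)[:n_trios]
    C = np.concatenate(parts_C)[:n_trios]
    return TrioGenotypes(M=M, F=F, C=C)


def mask_genotypes(trios: TrioGenotypes, rate: float,
                   rng: np.random.Generator) -> TrioGenotypes:
    """Set each individual-locus genotype missing independently at ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return trios
    shape = trios.M.shape
    out = []
    for a in (trios.M, trios.F, trios.C):
        drop = rng.random(shape) < rate
        out.append(np.where(drop, MISSING, a))
    return TrioGenotypes(M=out[0], F=out[1], C=out[2], snp_ids=trios.snp_ids)
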