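"""Forward-time Wright-Fisher simulation of ancestry tracts under a
single pulse of admixture.

Model
-----
At generation 0 the admixed population is founded by ``2 Ne`` haplotypes,
each a single-ancestry genome whose ancestry is drawn i.i.d. from the
admixture proportions (a single pulse: no later migration).  Each
subsequent generation is formed by Wright-Fisher resampling: every
offspring picks two parents uniformly at random with replacement (or one
from each sex pool in ``two_sex`` mode) and receives one recombinant
gamete from each.  Meiosis places a Poisson(length in Morgans) number of
crossovers per chromosome, uniformly and without interference, and
chromosomes assort independently.  After ``T`` generations, ``n_sample``
diploids are drawn without replacement.

State is tract-based: a haplotype is a list of ancestry intervals, not a
per-SNP vector, so population sizes in the thousands over tens of
generations are cheap.  Internally all chromosomes are concatenated onto
one genetic coordinate axis; independent assortment is realised as a
fair-coin switch point at each chromosome boundary, which is equivalent
to an independent starting phase per chromosome.  SNPs are projected onto
tracts only for the final sample, preserving the spatial autocorrelation
of local ancestry along each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from admixscan.io import AncestryCalls, AncestryLabelSet, DimensionError, SnpMap

__all__ = [
    "GenomeModel",
    "AdmixtureConfig",
    "TractGenome",
    "SimulatedSample",
    "meiosis",
    "simulate_population",
    "physical_to_genetic",
    "project_tracts_to_snps",
    "default_chile_genome",
    "replicate_rng",
]

DEFAULT_PROPORTIONS: dict[str, float] = {"EUR": 0.521, "NAM": 0.442, "AFR": 0.037}


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with genetic (Morgan) and physical (bp) lengths."""

    chroms: tuple[tuple[str, float, int], ...]  # (name, length_M, length_bp)

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length_m, length_bp in self.chroms:
            if length_m <= 0 or length_bp <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def n_chroms(self) -> int:
        return len(self.chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.chroms)

    @property
    def lengths_M(self) -> np.ndarray:
        return np.array([c[1] for c in self.chroms])

    @property
    def total_length_M(self) -> float:
        return float(self.lengths_M.sum())

    @property
    def offsets_M(self) -> np.ndarray:
        """Global genetic coordinate of each chromosome's start."""
        return np.concatenate(([0.0], np.cumsum(self.lengths_M)[:-1]))

    @property
    def boundaries_M(self) -> np.ndarray:
        """Internal chromosome boundaries on the concatenated axis."""
        return np.cumsum(self.lengths_M)[:-1]

    def chrom_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in genome") from None


@dataclass(frozen=True)
class AdmixtureConfig:
    """Single-pulse admixture scenario.

    Defaults follow the three-way European / Native American / African
    admixture of Chileans: proportions 0.521 / 0.442 / 0.037, T = 10
    generations since the pulse, Ne = 4,500 diploids, 185 sampled diploids
    (K = 370 haplotypes).  Proportions are normalized to sum to one.
    """

    proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    T: int = 10
    Ne: int = 4500
    n_sample: int = 185
    mating: str = "hermaphrodite"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.Ne <= 1:
            raise ValueError("Ne must be > 1 diploid")
        if not 1 <= self.n_sample <= self.Ne:
            raise ValueError(f"n_sample must be in [1, Ne={self.Ne}], got {self.n_sample}")
        if self.mating not in ("hermaphrodite", "two_sex"):
            raise ValueError("mating must be 'hermaphrodite' or 'two_sex'")
        total = float(sum(self.proportions.values()))
        if total <= 0 or any(v < 0 for v in self.proportions.values()):
            raise ValueError("proportions must be non-negative with a positive sum")

    @property
    def labels(self) -> AncestryLabelSet:
        return AncestryLabelSet(tuple(self.proportions))

    @property
    def normalized_proportions(self) -> np.ndarray:
        v = np.array(list(self.proportions.values()), dtype=float)
        return v / v.sum()


class TractGenome:
    """One haplotype as ancestry tracts on the concatenated genetic axis.

    ``breaks`` are the strictly increasing interior junction positions (in
    Morgans, global coordinates) and ``anc[i]`` is the ancestry code of the
    half-open segment between ``breaks[i-1]`` and ``breaks[i]``.  The form
    is junction-minimal: adjacent segments always differ in ancestry.
    """

    __slots__ = ("breaks", "anc", "genome")

    def __init__(self, breaks: np.ndarray, anc: np.ndarray, genome: GenomeModel):
        self.breaks = np.asarray(breaks, dtype=np.float64)
        self.anc = np.asarray(anc, dtype=np.int8)
        self.genome = genome

    @classmethod
    def uniform(cls, ancestry_code: int, genome: GenomeModel) -> "TractGenome":
        """A founder haplotype: one ancestry everywhere."""
        return cls(np.empty(0), np.array([ancestry_code], dtype=np.int8), genome)

    def validate(self) -> None:
        if self.anc.size != self.breaks.size + 1:
            raise ValueError("anc must have one more entry than breaks")
        if self.breaks.size:
            if np.any(np.diff(self.breaks) <= 0):
                raise ValueError("breaks must be strictly increasing")
            if self.breaks[0] <= 0 or self.breaks[-1] >= self.genome.total_length_M:
                raise ValueError("breaks must lie strictly inside the genome")
        if np.any(self.anc[1:] == self.anc[:-1]):
            raise ValueError("adjacent tracts share an ancestry; not canonical")

    def ancestry_at(self, gpos_global: np.ndarray) -> np.ndarray:
        """Ancestry code at global genetic positions (half-open tracts)."""
        idx = np.searchsorted(self.breaks, gpos_global, side="right")
        return self.anc[idx]

    def tracts(self, chrom: str) -> list[tuple[float, float, int]]:
        """Tracts of one chromosome as (start_M, end_M, code), local coordinates."""
        ci = self.genome.chrom_index(chrom)
        lo = float(self.genome.offsets_M[ci])
        hi = lo + float(self.genome.lengths_M[ci])
        i0 = int(np.searchsorted(self.breaks, lo, side="right"))
        i1 = int(np.searchsorted(self.breaks, hi, side="left"))
        pts = [lo, *self.breaks[i0:i1], hi]
        return [(pts[k] - lo, pts[k + 1] - lo, int(self.anc[i0 + k]))
                for k in range(len(pts) - 1)]

    @property
    def n_junctions(self) -> int:
        """Within-chromosome ancestry junctions (boundary-coincident breaks excluded)."""
        if not self.breaks.size:
            return 0
        return int((~np.isin(self.breaks, self.genome.boundaries_M)).sum())


@dataclass
class SimulatedSample:
    """Haplotypes sampled from the final generation, plus provenance."""

    config: AdmixtureConfig
    genome: GenomeModel
    haplotypes: list[TractGenome]  # 2 * n_sample, individual j owns 2j, 2j+1
    founder_proportions: dict[str, float]
    sample_ids: list[str]
    sex: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.haplotypes) != 2 * self.config.n_sample:
            raise DimensionError("expected 2 haplotypes per sampled diploid")


# ---------------------------------------------------------------------------
# meiosis

def _recombine(bp_a, anc_a, bp_b, anc_b, switch, phase):
    """Splice two haplotypes at the given sorted switch points.

    Segments between switch points come alternately from parent a and b,
    starting from a when phase == 0.  Output is junction-minimal.
    """
    if switch.size == 0:
        return (bp_a, anc_a) if phase == 0 else (bp_b, anc_b)
    pts = np.unique(np.concatenate((switch, bp_a, bp_b)))
    starts = np.concatenate(((0.0,), pts))
    from_b = ((np.searchsorted(switch, starts, side="right") + phase) % 2).astype(bool)
    anc = np.where(from_b,
                   anc_b[np.searchsorted(bp_b, starts, side="right")],
                   anc_a[np.searchsorted(bp_a, starts, side="right")])
    change = anc[1:] != anc[:-1]
    return pts[change], np.concatenate((anc[:1], anc[1:][change]))


def _draw_switch_points(rng, total_length, boundaries):
    """Crossovers (Poisson per Morgan, uniform, no interference) plus a
    fair-coin assortment switch at each chromosome boundary."""
    n_x = rng.poisson(total_length)
    cuts = rng.uniform(0.0, total_length, n_x)
    if boundaries.size:
        cuts = np.concatenate((cuts, boundaries[rng.random(boundaries.size) < 0.5]))
    cuts.sort()
    return cuts


def meiosis(parent_hap_a: TractGenome, parent_hap_b: TractGenome,
            genome: GenomeModel, rng: np.random.Generator) -> TractGenome:
    """One gamete from a diploid parent's two haplotypes.

    Per chromosome the crossover count is Poisson in its Morgan length with
    i.i.d. uniform positions; the gamete alternates parental segments from
    a fair-coin starting phase, and chromosomes assort independently.
    """
    if parent_hap_a.genome != genome or parent_hap_b.genome != genome:
        raise DimensionError("parental haplotypes do not tile the given genome")
    switch = _draw_switch_points(rng, genome.total_length_M, genome.boundaries_M)
    phase = int(rng.integers(0, 2))
    bp, anc = _recombine(parent_hap_a.breaks, parent_hap_a.anc,
                         parent_hap_b.breaks, parent_hap_b.anc, switch, phase)
    return TractGenome(bp, anc, genome)


# ---------------------------------------------------------------------------
# population simulation

def replicate_rng(seed: int, replicate: int = 0) -> np.random.Generator:
    """Independent child stream for one replicate of a batch.

    Splitting rule: ``SeedSequence(seed).spawn()``-style keying by the
    replicate index, so any subset of replicates can be reproduced.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(replicate,)))


def _draw_sexes(rng, n: int) -> np.ndarray:
    for _ in range(100):
        sexes = rng.integers(0, 2, n)  # 0 = female, 1 = male
        if 0 < sexes.sum() < n:
            return sexes
    raise RuntimeError("could not draw a population containing both sexes")


def simulate_population(config: AdmixtureConfig, genome: GenomeModel,
                        seed: int | None = None) -> SimulatedSample:
    """Run the single-pulse Wright-Fisher scenario and sample diploids.

    The same (config, genome, seed) triple reproduces the output exactly.
    ``two_sex`` mating draws each generation's sexes at random, mothers
    from the female pool and fathers from the male pool; on autosomes this
    is ancestry-neutral and exists for fidelity to sex-labelled samples.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    props = config.normalized_proportions
    n_labels = len(props)
    ne, t_gen = config.Ne, config.T
    total_l = genome.total_length_M
    boundaries = genome.boundaries_M

    founder_anc = rng.choice(n_labels, size=2 * ne, p=props)
    empty = np.empty(0)
    pop: list[tuple[np.ndarray, np.ndarray]] = [
        (empty, np.array([a], dtype=np.int8)) for a in founder_anc]
    sexes = _draw_sexes(rng, ne) if config.mating == "two_sex" else None

    for _ in range(t_gen):
        if sexes is None:
            mothers = rng.integers(0, ne, ne)
            fathers = rng.integers(0, ne, ne)
        else:
            females = np.flatnonzero(sexes == 0)
            males = np.flatnonzero(sexes == 1)
            mothers = females[rng.integers(0, females.size, ne)]
            fathers = males[rng.integers(0, males.size, ne)]
        new_pop: list[tuple[np.ndarray, np.ndarray]] = []
        for m, f in zip(mothers, fathers):
            for parent in (m, f):
                switch = _draw_switch_points(rng, total_l, boundaries)
                phase = int(rng.integers(0, 2))
                ha, hb = pop[2 * parent], pop[2 * parent + 1]
                new_pop.append(_recombine(ha[0], ha[1], hb[0], hb[1], switch, phase))
        pop = new_pop
        if sexes is not None:
            sexes = _draw_sexes(rng, ne)

    picked = rng.choice(ne, size=config.n_sample, replace=False)
    haplotypes = []
    for j in picked:
        for h in (2 * j, 2 * j + 1):
            haplotypes.append(TractGenome(pop[h][0], pop[h][1], genome))
    labels = config.labels
    counts = np.bincount(founder_anc, minlength=n_labels)
    founder_props = {lab: counts[i] / (2 * ne) for i, lab in enumerate(labels.labels)}
    sample_ids = [f"sim{j + 1:05d}" for j in range(config.n_sample)]
    sex_labels = None
    if sexes is not None:
        sex_labels = ["F" if sexes[j] == 0 else "M" for j in picked]
    return SimulatedSample(config=config, genome=genome, haplotypes=haplotypes,
                           founder_proportions=founder_props,
                           sample_ids=sample_ids, sex=sex_labels)


# ---------------------------------------------------------------------------
# SNP projection

def physical_to_genetic(snp_map: SnpMap, genome: GenomeModel) -> SnpMap:
    """Fill genetic positions by linear bp -> Morgan scaling per chromosome.

    No genetic map is assumed: gpos_M = length_M * pos_bp / length_bp, which
    preserves SNP order and the relative spacing of the physical map.
    """
    gpos = np.empty(len(snp_map))
    chrom_info = {name: (lm, lbp) for name, lm, lbp in genome.chroms}
    chroms = snp_map.chrom
    pos = snp_map.pos_bp
    for i in range(len(snp_map)):
        try:
            lm, lbp = chrom_info[chroms[i]]
        except KeyError:
            raise KeyError(f"chromosome {chroms[i]!r} not in genome model") from None
        if pos[i] > lbp:
            raise ValueError(
                f"SNP {snp_map.snp_id[i]} at {pos[i]} bp exceeds {chroms[i]} "
                f"length {lbp} bp")
        gpos[i] = lm * pos[i] / lbp
    return snp_map.with_gpos(gpos)


def project_tracts_to_snps(sample: SimulatedSample, snp_map: SnpMap) -> AncestryCalls:
    """Read each haplotype's tract ancestry off at every SNP position.

    Tracts are half-open [start, end): a SNP exactly at a junction takes the
    tract that starts there; a SNP at the very end of a chromosome takes the
    chromosome's last tract.
    """
    if not snp_map.has_gpos:
        raise ValueError("snp_map lacks genetic positions; run physical_to_genetic first")
    genome = sample.genome
    idx = np.array([genome.chrom_index(c) for c in snp_map.chrom])
    lengths = genome.lengths_M[idx]
    gpos = snp_map.gpos_M
    if np.any(gpos > lengths):
        bad = int(np.argmax(gpos > lengths))
        raise ValueError(
            f"SNP {snp_map.snp_id[bad]} gpos {gpos[bad]} M exceeds chromosome "
            f"genetic length {lengths[bad]} M")
    # chromosome-end SNPs belong to the last tract, not the next chromosome
    g_global = genome.offsets_M[idx] + np.minimum(gpos, np.nextafter(lengths, 0.0))
    calls = np.empty((len(sample.haplotypes), len(snp_map)), dtype=np.int8)
    for h, hap in enumerate(sample.haplotypes):
        calls[h] = hap.ancestry_at(g_global)
    return AncestryCalls(snp_map=snp_map, labels=sample.config.labels, calls=calls,
                         sample_ids=list(sample.sample_ids), sex=sample.sex)


# ---------------------------------------------------------------------------
# default genome

def default_chile_genome(n_snps: int, seed: int | None = None, *,
                         n_chroms: int = 189, chrom_morgans: float = 0.2,
                         chrom_bp: int = 15_000_000) -> tuple[GenomeModel, SnpMap]:
    """Genome of 189 equal chromosomes with uniformly placed SNPs.

    The default 0.2 M per chromosome makes the total genetic length 37.8 M,
    close to the human autosomal map; a literal 20 M per chromosome is
    available through ``chrom_morgans`` for a much longer genome.  SNP bp
    positions are drawn uniformly over the concatenated physical genome
    (no duplicates), sorted, and given genetic positions by linear scaling.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    rng = np.random.default_rng(seed)
    genome = GenomeModel(tuple(
        (f"chr{c + 1:03d}", float(chrom_morgans), int(chrom_bp))
        for c in range(n_chroms)))
    total_bp = n_chroms * chrom_bp
    if n_snps > total_bp:
        raise ValueError("more SNPs requested than available bp positions")
    glob = np.unique(rng.integers(0, total_bp, size=n_snps))
    while glob.size < n_snps:
        extra = rng.integers(0, total_bp, size=n_snps - glob.size)
        glob = np.unique(np.concatenate((glob, extra)))
    glob.sort()
    chrom_idx = glob // chrom_bp
    pos_bp = (glob % chrom_bp) + 1  # 1-based
    names = [f"chr{c + 1:03d}" for c in chrom_idx]
    snp_ids = [f"chr{c + 1:03d}_{p}" for c, p in zip(chrom_idx, pos_bp)]
    snp_map = SnpMap(snp_ids, names, pos_bp)
    return genome, physical_to_genetic(snp_map, genome)
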