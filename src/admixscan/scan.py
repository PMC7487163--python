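"""Per-SNP local-ancestry deviation scan.

At every SNP the observed fraction ``p_hat`` of haplotypes carrying the
target ancestry (out of K = 2n sampled haplotypes) is compared with the
genome-wide mean ``p0``.  Under the null hypothesis that the SNP's true
ancestry proportion equals ``p0``, the count of target-ancestry haplotypes
is Binomial(K, p0), and the binomial-MLE asymptotics give a normal test
statistic.  Three variants are provided:

``score``  (default)  z = (p_hat - p0) / sqrt(p0 (1 - p0) / K), normal tail;
``wald``              same numerator with SE evaluated at p_hat;
``t``                 the score statistic referred to Student-t on K-1 df.

At K = 370 all three agree to displayed precision.  The default tail is
``upper`` (an excess of the target ancestry); an ancestry deficit or a
two-sided scan are options.  Significance is a fixed per-SNP threshold
(default 1e-5) with no further multiple-testing correction: the
genome-wide decision is delegated to neutral simulation (see
:mod:`admixscan.nullcal`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from admixscan.io import AncestryCalls

__all__ = [
    "ScanConfig",
    "ScanResult",
    "genome_wide_mean",
    "snp_mean_ancestry",
    "deviation_test",
    "run_scan",
    "significant_regions",
]

_TAILS = ("upper", "lower", "two_sided")
_STATISTICS = ("score", "wald", "t")

# smallest representable positive tail mass; p-values are clamped to (TINY, 1]
_TINY = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings: target ancestry, null proportion, tail, statistic, alpha.

    ``p0="auto"`` (the default) uses the realized genome-wide mean of the
    target ancestry, mirroring how a real scan takes its null from the
    sample itself; a fixed numeric p0 is accepted.
    """

    target_label: str = "EUR"
    p0: float | str = "auto"
    tail: str = "upper"
    statistic: str = "score"
    alpha: float = 1e-5

    def __post_init__(self) -> None:
        if isinstance(self.p0, str):
            if self.p0 != "auto":
                raise ValueError(f"p0 must be a number or 'auto', got {self.p0!r}")
        elif not 0.0 < self.p0 < 1.0:
            raise ValueError(f"fixed p0 must be in (0, 1), got {self.p0}")
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"statistic must be one of {_STATISTICS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ScanResult:
    """Per-SNP scan table plus the scalars the test was run with."""

    table: pd.DataFrame  # snp_id, chrom, pos_bp, p_hat, z, p_value, significant
    n_haplotypes: int
    p0_used: float
    config: ScanConfig = field(repr=False, default=ScanConfig())

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def min_p(self) -> float:
        return float(self.table["p_value"].min())

    def top_hit(self) -> pd.Series:
        """Row of the SNP with the largest signed deviation p_hat - p0."""
        return self.table.loc[(self.table["p_hat"] - self.p0_used).idxmax()]


def genome_wide_mean(calls: AncestryCalls, target_label: str) -> float:
    """Mean of the target-ancestry indicator over all haplotype x SNP cells."""
    code = calls.labels.code_of(target_label)
    return float(np.mean(calls.calls == code))


def snp_mean_ancestry(calls: AncestryCalls, target_label: str) -> np.ndarray:
    """Per-SNP observed ancestry fraction p_hat_i = (target count at SNP i) / K."""
    code = calls.labels.code_of(target_label)
    return (calls.calls == code).mean(axis=0)


def deviation_test(p_hat, K: int, p0: float, tail: str = "upper",
                   statistic: str = "score") -> tuple[np.ndarray, np.ndarray]:
    """Test H0: p_i = p0 against the chosen alternative at each SNP.

    Vectorized over ``p_hat``.  Returns ``(z, p_value)`` arrays; p-values
    are clamped to the smallest positive representable tail so downstream
    log transforms never hit zero.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    if K < 2 or K % 2:
        raise ValueError(f"K must be an even count of haplotypes >= 2, got {K}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    p_hat = np.asarray(p_hat, dtype=np.float64)

    se0 = np.sqrt(p0 * (1.0 - p0) / K)
    if statistic == "wald":
        var_hat = p_hat * (1.0 - p_hat) / K
        degenerate = var_hat == 0.0
        if np.any(degenerate):
            warnings.warn(
                "wald statistic undefined at p_hat in {0, 1}; "
                "falling back to the score SE there", RuntimeWarning, stacklevel=2)
        se = np.where(degenerate, se0, np.sqrt(var_hat))
    else:
        se = se0
    z = (p_hat - p0) / se

    if statistic == "t":
        dist_sf = lambda x: stats.t.sf(x, df=K - 1)  # noqa: E731
        dist_cdf = lambda x: stats.t.cdf(x, df=K - 1)  # noqa: E731
    else:
        dist_sf, dist_cdf = stats.norm.sf, stats.norm.cdf

    if tail == "upper":
        p = dist_sf(z)
    elif tail == "lower":
        p = dist_cdf(z)
    else:
        p = 2.0 * dist_sf(np.abs(z))
    p = np.clip(p, _TINY, 1.0)
    return z, p


def run_scan(calls: AncestryCalls, config: ScanConfig = ScanConfig()) -> ScanResult:
    """Scan every SNP for a deviation of the target ancestry from p0."""
    p0 = genome_wide_mean(calls, config.target_label) if config.p0 == "auto" \
        else float(config.p0)
    if not 0.0 < p0 < 1.0:
        raise ValueError(
            f"genome-wide mean of {config.target_label!r} is {p0}; the deviation "
            "test needs an interior null proportion")
    p_hat = snp_mean_ancestry(calls, config.target_label)
    K = calls.n_haplotypes
    z, p = deviation_test(p_hat, K, p0, tail=config.tail, statistic=config.statistic)
    table = pd.DataFrame({
        "snp_id": calls.snp_map.snp_id,
        "chrom": calls.snp_map.chrom,
        "pos_bp": calls.snp_map.pos_bp,
        "p_hat": p_hat,
        "z": z,
        "p_value": p,
        "significant": p < config.alpha,
    })
    return ScanResult(table=table, n_haplotypes=K, p0_used=p0, config=config)


def significant_regions(scan_result: ScanResult, max_gap_bp: int = 500_000) -> pd.DataFrame:
    """Group significant SNPs into regions.

    A region is a maximal run of significant SNPs on one chromosome in which
    consecutive significant SNPs are at most ``max_gap_bp`` apart.  Returns a
    table (chrom, start_bp, end_bp, n_snps, min_p), empty when nothing is
    significant.
    """
    cols = ["chrom", "start_bp", "end_bp", "n_snps", "min_p"]
    sig = scan_result.table[scan_result.table["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    regions = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        pval = sub["p_value"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp) + 1
        for idx in np.split(np.arange(len(pos)), breaks):
            regions.append({
                "chrom": chrom,
                "start_bp": int(pos[idx[0]]),
                "end_bp": int(pos[idx[-1]]),
                "n_snps": int(len(idx)),
                "min_p": float(pval[idx].min()),
            })
    return pd.DataFrame(regions, columns=cols)


def write_scan_table(result: ScanResult, path) -> None:
    """Write the per-SNP scan table as TSV with a format-version header."""
    with open(path, "w") as fh:
        fh.write("#admixscan scan v1\n")
        result.table.to_csv(fh, sep="\t", index=False)


def plot_scan(result: ScanResult, path, genome_order: list[str] | None = None) -> None:
    """Render ancestry-mean and -log10(p) tracks over concatenated chromosomes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    chroms = genome_order or list(dict.fromkeys(t["chrom"]))
    offsets, off = {}, 0
    for c in chroms:
        offsets[c] = off
        off += int(t.loc[t["chrom"] == c, "pos_bp"].max())
    x = t["pos_bp"].to_numpy() + np.array([offsets[c] for c in t["chrom"]])

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(12, 6), sharex=True)
    ax1.scatter(x, t["p_hat"], s=2, c="steelblue")
    ax1.axhline(result.p0_used, color="grey", lw=1, ls="--")
    ax1.set_ylabel(f"{result.config.target_label} ancestry")
    ax2.scatter(x, -np.log10(t["p_value"]), s=2, c="firebrick")
    ax2.axhline(-np.log10(result.config.alpha), color="grey", lw=1, ls="--")
    ax2.set_ylabel("-log10 p")
    ax2.set_xlabel("concatenated genome position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
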