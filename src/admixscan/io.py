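"""Data model and file formats for local-ancestry call matrices.

The pipeline starts downstream of local-ancestry inference: its raw input
is a haplotype-by-SNP matrix of integer ancestry codes tied to a SNP map.
Two on-disk dialects are supported:

``tsv``
    A header row of SNP ids followed by one whitespace-separated row of
    integer codes per haplotype.  Haplotypes ``2j`` and ``2j+1`` belong to
    diploid individual ``j``.

``lampld``
    One line per diploid individual, a whitespace-free string of digits
    with two digits per SNP (the pair of haplotype codes for that SNP, in
    haplotype order).  LAMP-LD-style output codes each allele as 0, 1 or 2
    for a three-way panel; the exact layout of LAMP-LD files is not
    standardised, so the dialect is explicit and never guessed.

Both writers emit ``#admixscan ... v1`` comment headers; readers skip any
``#`` comment line, and recover sample ids (and optional per-individual
sex labels) from ``#samples`` / ``#sex`` comments when present.

Missing ancestry calls are not supported: every cell must decode to a
valid code, and a malformed cell is a :class:`ParseError` naming its line
and column, never an imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FORMAT_VERSION = "v1"

__all__ = [
    "AdmixscanError",
    "ParseError",
    "DimensionError",
    "AncestryLabelSet",
    "SnpMap",
    "AncestryCalls",
    "DosageMatrix",
    "dosage",
    "read_snp_map",
    "write_snp_map",
    "read_ancestry_calls",
    "write_ancestry_calls",
]


class AdmixscanError(Exception):
    """Base class for errors raised by this package."""


class ParseError(AdmixscanError):
    """A file cell could not be decoded; carries 1-based line and column."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


class DimensionError(AdmixscanError):
    """Shapes of related objects (calls, map, labels) disagree."""


@dataclass(frozen=True)
class AncestryLabelSet:
    """Ordered ancestry labels; label i carries integer code i.

    The default three-way set matches the usual European / Native American /
    African coding of LAMP-LD output (EUR -> 0, NAM -> 1, AFR -> 2).
    """

    labels: tuple[str, ...] = ("EUR", "NAM", "AFR")

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("need at least one ancestry label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate ancestry labels: {self.labels}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def code(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def code_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ancestry label {label!r}; known: {self.labels}") from None


class SnpMap:
    """SNP map: id, chromosome, 1-based physical position, optional genetic position.

    Genetic positions are stored in Morgans.  Rows are kept in file order,
    which must be grouped by chromosome with strictly increasing ``pos_bp``
    (and non-decreasing ``gpos_M`` where present) within each chromosome.
    """

    COLUMNS = ("snp_id", "chrom", "pos_bp", "gpos_M")

    def __init__(self, snp_id: Sequence[str], chrom: Sequence[str],
                 pos_bp: Sequence[int], gpos_M: Sequence[float] | None = None):
        n = len(snp_id)
        if gpos_M is None:
            gpos_M = np.full(n, np.nan)
        self.df = pd.DataFrame({
            "snp_id": pd.array(snp_id, dtype="str"),
            "chrom": pd.array(chrom, dtype="str"),
            "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            "gpos_M": np.asarray(gpos_M, dtype=np.float64),
        })
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        if (df["pos_bp"] < 1).any():
            raise ValueError("pos_bp must be >= 1 (1-based positions)")
        g = df["gpos_M"].to_numpy()
        if np.any(g[~np.isnan(g)] < 0):
            raise ValueError("gpos_M must be >= 0")
        chrom_arr = df["chrom"].to_numpy()
        block_start = np.concatenate(([0], np.flatnonzero(chrom_arr[1:] != chrom_arr[:-1]) + 1))
        block_names = chrom_arr[block_start]
        if len(set(block_names)) != len(block_names):
            dup = pd.Series(block_names)[pd.Series(block_names).duplicated()].iloc[0]
            raise ValueError(f"chromosome {dup!r} appears in disjoint blocks")
        for lo, hi in zip(block_start, np.append(block_start[1:], len(df))):
            chrom = chrom_arr[lo]
            pos = df["pos_bp"].to_numpy()[lo:hi]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on {chrom!r}")
            gg = df["gpos_M"].to_numpy()[lo:hi]
            gg = gg[~np.isnan(gg)]
            if gg.size > 1 and np.any(np.diff(gg) < 0):
                raise ValueError(f"gpos_M decreasing on {chrom!r}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpMap):
            return NotImplemented
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        same = (a["snp_id"].tolist() == b["snp_id"].tolist()
                and a["chrom"].tolist() == b["chrom"].tolist()
                and np.array_equal(a["pos_bp"], b["pos_bp"]))
        ga, gb = a["gpos_M"].to_numpy(), b["gpos_M"].to_numpy()
        return same and np.array_equal(ga, gb, equal_nan=True)

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    @property
    def gpos_M(self) -> np.ndarray:
        return self.df["gpos_M"].to_numpy()

    @property
    def has_gpos(self) -> bool:
        return bool(np.all(~np.isnan(self.df["gpos_M"].to_numpy())))

    def with_gpos(self, gpos_M: np.ndarray) -> "SnpMap":
        return SnpMap(self.snp_id, self.chrom, self.pos_bp, np.asarray(gpos_M, float))


@dataclass
class AncestryCalls:
    """Haplotype x SNP matrix of ancestry codes tied to a SNP map.

    Row ``2j`` and ``2j+1`` are the two haplotypes of diploid individual
    ``sample_ids[j]``; the total haplotype count K = 2n.  ``sex`` is
    optional per-individual metadata and never enters any computation.
    """

    snp_map: SnpMap
    labels: AncestryLabelSet
    calls: np.ndarray
    sample_ids: list[str]
    sex: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise DimensionError(f"calls must be 2-D, got shape {self.calls.shape}")
        if not np.issubdtype(self.calls.dtype, np.integer):
            raise ValueError("calls must be an integer matrix")
        n_hap, n_snp = self.calls.shape
        if n_hap == 0 or n_snp == 0:
            raise DimensionError("empty ancestry-call matrix")
        if n_hap % 2:
            raise DimensionError(f"haplotype count {n_hap} is odd; expected 2 per individual")
        if n_hap != 2 * len(self.sample_ids):
            raise DimensionError(
                f"{n_hap} haplotypes but {len(self.sample_ids)} sample ids (expected 2 per id)")
        if n_snp != len(self.snp_map):
            raise DimensionError(f"{n_snp} call columns but {len(self.snp_map)} SNPs in map")
        if self.calls.min() < 0 or self.calls.max() >= len(self.labels):
            bad = self.calls[(self.calls < 0) | (self.calls >= len(self.labels))][0]
            raise ValueError(f"invalid ancestry code {bad} for {len(self.labels)} labels")
        if self.sex is not None and len(self.sex) != len(self.sample_ids):
            raise DimensionError("sex labels must match individual count")

    @property
    def n_haplotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AncestryCalls):
            return NotImplemented
        return (self.snp_map == other.snp_map
                and self.labels == other.labels
                and np.array_equal(self.calls, other.calls)
                and self.sample_ids == other.sample_ids
                and self.sex == other.sex)


@dataclass(frozen=True)
class DosageMatrix:
    """Per-individual count (0/1/2) of haplotypes carrying the target ancestry."""

    target_label: str
    X: np.ndarray
    sample_ids: tuple[str, ...] = field(default=())

    @property
    def column_fraction(self) -> np.ndarray:
        """Per-SNP fraction of target-ancestry haplotypes, sum(X) / 2n."""
        return self.X.sum(axis=0) / (2 * self.X.shape[0])


def dosage(calls: AncestryCalls, target_label: str) -> DosageMatrix:
    """Collapse haplotype calls to per-individual target-ancestry dosages.

    ``X[j, i]`` counts how many of individual j's two haplotypes carry the
    target ancestry at SNP i; summing dosage matrices over all labels gives
    the constant 2 everywhere.
    """
    code = calls.labels.code_of(target_label)
    ind = (calls.calls == code).astype(np.int8)
    X = ind.reshape(calls.n_individuals, 2, calls.n_snps).sum(axis=1)
    return DosageMatrix(target_label, X, tuple(calls.sample_ids))


# ---------------------------------------------------------------------------
# SNP map I/O

def write_snp_map(snp_map: SnpMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#admixscan snp-map {FORMAT_VERSION}\n")
        fh.write("snp_id\tchrom\tpos_bp\tgpos_M\n")
        for sid, chrom, pos, g in zip(snp_map.snp_id, snp_map.chrom,
                                      snp_map.pos_bp, snp_map.gpos_M):
            gs = "NA" if np.isnan(g) else repr(float(g))
            fh.write(f"{sid}\t{chrom}\t{pos}\t{gs}\n")


def read_snp_map(path: str | Path) -> SnpMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "chrom": str},
                     na_values=["NA"])
    missing = set(SnpMap.COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"SNP map at {path} lacks columns {sorted(missing)}")
    return SnpMap(df["snp_id"], df["chrom"], df["pos_bp"], df["gpos_M"])


# ---------------------------------------------------------------------------
# Ancestry-call I/O

def _auto_sample_ids(n_ind: int) -> list[str]:
    return [f"I{j + 1:04d}" for j in range(n_ind)]


def write_ancestry_calls(calls: AncestryCalls, path: str | Path, dialect: str = "tsv") -> None:
    """Write a call matrix in the ``tsv`` or ``lampld`` dialect.

    The written file round-trips through :func:`read_ancestry_calls` (with
    the same SNP map and label set) to a bit-identical object.
    """
    if dialect not in ("tsv", "lampld"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if calls.n_snps == 0 or calls.n_haplotypes == 0:
        raise DimensionError("refusing to write an empty call matrix")
    if dialect == "lampld" and len(calls.labels) > 10:
        raise ValueError("lampld dialect encodes one digit per code; <=10 labels required")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#admixscan ancestry-calls {FORMAT_VERSION} dialect={dialect} "
                 f"labels={','.join(calls.labels.labels)}\n")
        fh.write("#samples\t" + "\t".join(calls.sample_ids) + "\n")
        if calls.sex is not None:
            fh.write("#sex\t" + "\t".join(calls.sex) + "\n")
        if dialect == "tsv":
            fh.write("\t".join(calls.snp_map.snp_id) + "\n")
            np.savetxt(fh, calls.calls, fmt="%d", delimiter="\t")
        else:
            # two digits per SNP per individual line: hap 2j then hap 2j+1
            m = calls.calls
            for j in range(calls.n_individuals):
                pair = np.empty(2 * calls.n_snps, dtype=m.dtype)
                pair[0::2] = m[2 * j]
                pair[1::2] = m[2 * j + 1]
                fh.write("".join(chr(48 + int(c)) for c in pair) + "\n")


def read_ancestry_calls(path: str | Path, dialect: str, snp_map: SnpMap,
                        labels: AncestryLabelSet | None = None) -> AncestryCalls:
    """Read a call matrix, validating codes and dimensions against the map."""
    if labels is None:
        labels = AncestryLabelSet()
    if dialect not in ("tsv", "lampld"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    sample_ids: list[str] | None = None
    sex: list[str] | None = None
    data_lines: list[tuple[int, str]] = []  # (1-based line number, text)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#samples\t"):
                    sample_ids = line.split("\t")[1:]
                elif line.startswith("#sex\t"):
                    sex = line.split("\t")[1:]
                continue
            data_lines.append((lineno, line))
    if not data_lines:
        raise ParseError(f"no data rows in {path}")

    n_snps = len(snp_map)
    if dialect == "tsv":
        rows = _parse_tsv_rows(data_lines, n_snps, len(labels), snp_map)
        hap_matrix = np.array(rows, dtype=np.int8)
    else:
        hap_matrix = _parse_lampld_rows(data_lines, n_snps, len(labels))

    n_hap = hap_matrix.shape[0]
    if n_hap % 2:
        raise DimensionError(f"{path}: odd haplotype count {n_hap}")
    if sample_ids is None:
        sample_ids = _auto_sample_ids(n_hap // 2)
    return AncestryCalls(snp_map=snp_map, labels=labels, calls=hap_matrix,
                         sample_ids=sample_ids, sex=sex)


def _parse_tsv_rows(data_lines, n_snps, n_labels, snp_map):
    first_fields = data_lines[0][1].split("\t") if "\t" in data_lines[0][1] \
        else data_lines[0][1].split()
    has_header = not all(_is_code(f) for f in first_fields)
    start = 0
    if has_header:
        if list(first_fields) != list(snp_map.snp_id):
            raise DimensionError("tsv header SNP ids do not match the SNP map")
        start = 1
    rows = []
    for lineno, line in data_lines[start:]:
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != n_snps:
            raise DimensionError(
                f"line {lineno}: {len(fields)} fields but SNP map has {n_snps} SNPs")
        row = []
        for col, f in enumerate(fields, start=1):
            if not _is_code(f) or not (0 <= int(f) < n_labels):
                raise ParseError(f"invalid ancestry code {f!r}", line=lineno, column=col)
            row.append(int(f))
        rows.append(row)
    return rows


def _parse_lampld_rows(data_lines, n_snps, n_labels):
    haps = np.empty((2 * len(data_lines), n_snps), dtype=np.int8)
    for r, (lineno, line) in enumerate(data_lines):
        s = line.strip()
        if len(s) != 2 * n_snps:
            raise DimensionError(
                f"line {lineno}: {len(s)} characters but expected {2 * n_snps} "
                f"(two per SNP for {n_snps} SNPs)")
        for col, ch in enumerate(s, start=1):
            if not ("0" <= ch <= "9") or int(ch) >= n_labels:
                raise ParseError(f"invalid ancestry code {ch!r}", line=lineno, column=col)
        codes = np.frombuffer(s.encode("ascii"), dtype=np.uint8) - 48
        haps[2 * r] = codes[0::2]
        haps[2 * r + 1] = codes[1::2]
    return haps


def _is_code(field: str) -> bool:
    return field.isdigit()
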