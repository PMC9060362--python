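"""Readers and writers for the standard file formats the tool touches.

PLINK 1 binary genotype triples (.bed/.bim/.fam), GCTA binary GRM triples
(.grm.bin/.grm.N.bin/.grm.id) and whitespace-delimited phenotype/covariate
tables.  Genotype access is lazy: the .bed payload is memory-mapped and only
the requested variant slice is decoded, so reading k variants touches
O(k * N / 4) bytes.

Decoded genotypes count copies of allele1 (the first allele column of the
.bim file); missing calls are the sentinel :data:`MISSING`.  Raw I/O is
lossless — mean imputation happens only inside the GRM computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in decoded integer matrices.
MISSING: int = -9

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# PLINK 1 2-bit codes, consumed low-order-first within each byte:
#   00 -> homozygous allele1 (2 copies), 01 -> missing,
#   10 -> heterozygous (1 copy),         11 -> homozygous allele2 (0 copies).
_CODE_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

# 256 x 4 lookup: byte value -> the four genotypes it encodes.
_BYTE_DECODE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _i in range(4):
        _BYTE_DECODE[_b, _i] = _CODE_TO_GENO[(_b >> (2 * _i)) & 0b11]


class FormatError(ValueError):
    """A file does not conform to its declared binary/text layout."""


@dataclass
class GenotypeDataset:
    """Lazy handle on an N x M genotype matrix with sample/variant metadata.

    Genotypes are integers in {0, 1, 2, MISSING}, counting allele1 copies.
    The accessor :meth:`genotypes` re-reads from the backing store on every
    call (read-only contract); in-memory datasets return copies.
    """

    sample_ids: list[tuple[str, str]]
    variants: list[tuple[str, str, float, int, str, str]]
    _array: np.ndarray | None = field(default=None, repr=False)
    _bed_path: Path | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @classmethod
    def from_array(
        cls,
        genotypes: np.ndarray,
        sample_ids: Sequence[tuple[str, str]] | None = None,
        variants: Sequence[tuple] | None = None,
    ) -> "GenotypeDataset":
        """Wrap an in-memory (N, M) integer matrix, synthesizing metadata."""
        g = np.asarray(genotypes)
        if g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x variants)")
        valid = np.isin(g, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(g[~valid])
            raise ValueError(f"genotype entries must be in {{0,1,2,{MISSING}}}; got {bad}")
        n, m = g.shape
        if sample_ids is None:
            sample_ids = [(f"F{i + 1}", f"I{i + 1}") for i in range(n)]
        if variants is None:
            variants = [("1", f"snp{j + 1}", 0.0, j + 1, "A", "B") for j in range(m)]
        if len(sample_ids) != n or len(variants) != m:
            raise ValueError("metadata length inconsistent with genotype matrix")
        return cls(
            sample_ids=[tuple(s) for s in sample_ids],
            variants=[tuple(v) for v in variants],
            _array=np.array(g, dtype=np.int8),
        )

    def genotypes(self, samples=None, variants=None) -> np.ndarray:
        """Return the (selected samples) x (selected variants) int8 matrix.

        ``samples``/``variants`` may be ``None`` (all), a slice, or an index
        array.  bed-backed datasets decode only the requested variant bytes.
        """
        if self._array is not None:
            out = self._array
            if variants is not None:
                out = out[:, variants]
            if samples is not None:
                out = out[samples, :]
            return out.copy()
        return self._read_bed_slice(samples, variants)

    def _read_bed_slice(self, samples, variants) -> np.ndarray:
        n, m = self.n_samples, self.n_variants
        bytes_per_variant = (n + 3) // 4
        vidx = np.arange(m)[variants] if variants is not None else np.arange(m)
        vidx = np.atleast_1d(vidx)
        raw = np.memmap(self._bed_path, dtype=np.uint8, mode="r", offset=3)
        cols = np.empty((len(vidx), n), dtype=np.int8)
        for out_j, j in enumerate(vidx):
            chunk = raw[j * bytes_per_variant : (j + 1) * bytes_per_variant]
            cols[out_j] = _BYTE_DECODE[chunk].reshape(-1)[:n]
        out = cols.T
        if samples is not None:
            out = out[samples, :]
        return np.ascontiguousarray(out)


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Open a PLINK 1 binary triple ``prefix``.bed/.bim/.fam lazily.

    Raises :class:`FileNotFoundError` for missing files and
    :class:`FormatError` for a wrong magic/mode byte or a .bed payload whose
    size disagrees with the .bim/.fam row counts.
    """
    prefix = Path(prefix)
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"required PLINK file not found: {f}")

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    if fam_df.shape[1] < 2:
        raise FormatError(f"{fam}: expected at least 2 columns (FID IID)")
    sample_ids = list(zip(fam_df[0], fam_df[1]))

    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    if bim_df.shape[1] != 6:
        raise FormatError(f"{bim}: expected 6 columns, got {bim_df.shape[1]}")
    variants = [
        (r[0], r[1], float(r[2]), int(r[3]), r[4], r[5])
        for r in bim_df.itertuples(index=False)
    ]

    with open(bed, "rb") as fh:
        header = fh.read(3)
    if len(header) < 3 or header[:2] != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes (not a PLINK 1 .bed file)")
    if header[2:3] != _BED_SNP_MAJOR:
        raise FormatError(f"{bed}: only SNP-major mode (0x01) is supported")

    n, m = len(sample_ids), len(variants)
    expected = 3 + ((n + 3) // 4) * m
    actual = bed.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{bed}: size {actual} bytes inconsistent with N={n}, M={m} "
            f"(expected {expected})"
        )
    return GenotypeDataset(sample_ids=sample_ids, variants=variants, _bed_path=bed)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``dataset`` as a PLINK 1 binary triple; read∘write is identity."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = dataset.n_samples

    with open(str(prefix) + ".fam", "w") as fh:
        for fid, iid in dataset.sample_ids:
            fh.write(f"{fid} {iid} 0 0 0 -9\n")
    with open(str(prefix) + ".bim", "w") as fh:
        for chrom, vid, cm, bp, a1, a2 in dataset.variants:
            fh.write(f"{chrom}\t{vid}\t{cm:g}\t{bp}\t{a1}\t{a2}\n")

    pad = (-n) % 4
    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        for j in range(dataset.n_variants):
            col = dataset.genotypes(variants=[j])[:, 0]
            codes = np.array([_GENO_TO_CODE[int(g)] for g in col], dtype=np.uint8)
            if pad:
                codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
            quads = codes.reshape(-1, 4)
            packed = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
            fh.write(packed.astype(np.uint8).tobytes())


@dataclass
class GRMFile:
    """A dense symmetric GRM with per-pair non-missing SNP counts."""

    values: np.ndarray
    pair_counts: np.ndarray
    sample_ids: list[tuple[str, str]]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(v, v.T, atol=1e-6):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(np.diag(v)).all():
            raise ValueError("GRM diagonal must be finite")
        self.values = v
        self.pair_counts = np.asarray(self.pair_counts)
        if self.pair_counts.shape != v.shape:
            raise ValueError("pair_counts shape must match values")
        if (self.pair_counts < 1).any():
            raise ValueError("pair_counts must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _tril_indices(n: int):
    # GCTA order: row-major lower triangle including the diagonal.
    rows, cols = [], []
    for i in range(n):
        rows.extend([i] * (i + 1))
        cols.extend(range(i + 1))
    return np.array(rows), np.array(cols)


def read_grm_gcta(prefix: str | Path) -> GRMFile:
    """Read a GCTA binary GRM triple ``prefix``.grm.bin/.grm.N.bin/.grm.id.

    The .bin files hold the lower triangle (diagonal included) row-major as
    little-endian float32; N is inferred from the .grm.id file.
    """
    prefix = Path(prefix)
    id_path = Path(str(prefix) + ".grm.id")
    bin_path = Path(str(prefix) + ".grm.bin")
    nbin_path = Path(str(prefix) + ".grm.N.bin")
    for f in (id_path, bin_path, nbin_path):
        if not f.exists():
            raise FileNotFoundError(f"required GRM file not found: {f}")

    ids = pd.read_csv(id_path, sep=r"\s+", header=None, dtype=str)
    n = len(ids)
    n_tri = n * (n + 1) // 2
    tri = np.fromfile(bin_path, dtype="<f4")
    if tri.size != n_tri:
        raise FormatError(
            f"{bin_path}: {tri.size} float32 values, expected N(N+1)/2 = {n_tri} for N={n}"
        )
    tri_n = np.fromfile(nbin_path, dtype="<f4")
    if tri_n.size not in (n_tri, 1):
        raise FormatError(f"{nbin_path}: {tri_n.size} values, expected {n_tri} (or 1)")

    rows, cols = _tril_indices(n)
    values = np.zeros((n, n))
    values[rows, cols] = tri
    values[cols, rows] = tri
    counts = np.zeros((n, n))
    if tri_n.size == 1:
        counts[:] = tri_n[0]
    else:
        counts[rows, cols] = tri_n
        counts[cols, rows] = tri_n
    return GRMFile(
        values=values,
        pair_counts=np.maximum(counts, 1).astype(np.int64),
        sample_ids=list(zip(ids[0], ids[1])),
    )


def write_grm_gcta(grm: GRMFile, prefix: str | Path) -> None:
    """Write ``grm`` in GCTA's binary layout; read∘write identity within float32."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n_samples
    rows, cols = _tril_indices(n)
    grm.values[rows, cols].astype("<f4").tofile(str(prefix) + ".grm.bin")
    grm.pair_counts[rows, cols].astype("<f4").tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for fid, iid in grm.sample_ids:
            fh.write(f"{fid}\t{iid}\n")


def read_table(path: str | Path, id_columns: int = 2) -> pd.DataFrame:
    """Read a whitespace-delimited table keyed by its first ``id_columns`` columns.

    The remaining columns must be numeric ("NA" parses to missing).  An
    optional single header line is detected by its non-numeric payload cells.
    Returns a DataFrame indexed by the id tuple; raises on duplicate ids and
    on non-numeric payload cells (naming the offending row/column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] <= id_columns:
        raise FormatError(f"{path}: expected more than {id_columns} columns")

    def _numeric_row(row) -> bool:
        for cell in row[id_columns:]:
            if str(cell).upper() in ("NA", "NAN", "."):
                continue
            try:
                float(cell)
            except (TypeError, ValueError):
                return False
        return True

    colnames = [f"id{i + 1}" for i in range(id_columns)]
    if not _numeric_row(df.iloc[0]):
        colnames += list(df.iloc[0, id_columns:])
        df = df.iloc[1:].reset_index(drop=True)
    else:
        colnames += [f"v{i + 1}" for i in range(df.shape[1] - id_columns)]
    df.columns = colnames

    for col in colnames[id_columns:]:
        cleaned = df[col].astype(str).str.upper().replace({"NA": None, "NAN": None, ".": None})
        try:
            df[col] = pd.to_numeric(cleaned)
        except (TypeError, ValueError):
            bad = cleaned[pd.to_numeric(cleaned, errors="coerce").isna() & cleaned.notna()]
            row = bad.index[0]
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            ) from None

    df.index = pd.MultiIndex.from_arrays(
        [df[c] for c in colnames[:id_columns]], names=colnames[:id_columns]
    )
    df = df.drop(columns=colnames[:id_columns])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate ids {dups}")
    return df


def align_table(
    table: pd.DataFrame, dataset: GenotypeDataset
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Reorder ``table`` rows to the dataset's sample order.

    Returns the aligned table (missing samples become NaN rows) and the list
    of table ids that matched no dataset sample — reported, never dropped
    silently.
    """
    target = pd.MultiIndex.from_tuples(dataset.sample_ids, names=table.index.names)
    aligned = table.reindex(target)
    unmatched = [tuple(ix) for ix in table.index if tuple(ix) not in set(dataset.sample_ids)]
    return aligned, unmatched
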