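"""Tabular input/output for pooled SNP count data and variant filtering.

All files are tab-separated UTF-8 text with ``#`` comment lines. Counts are
stored in long form, one row per site × SNP, with columns ``site, snp, y, n``
where ``y`` is the alt-allele count and ``n`` the total number of called
alleles at that SNP in that site's pooled sample. Missing site × SNP cells
simply have no row and are decoded as ``n = 0, y = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantCounts",
    "SnpMeta",
    "SiteSet",
    "CountsParseError",
    "read_counts",
    "write_counts",
    "read_sites",
    "write_sites",
    "read_snp_meta",
    "write_snp_meta",
    "read_frequencies",
    "write_frequencies",
    "filter_variants",
]

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


class CountsParseError(ValueError):
    """Raised when a counts/coordinates/metadata file violates its contract."""


@dataclass
class VariantCounts:
    """Pooled allele counts: ``y[j, i]`` alt alleles out of ``n[j, i]`` calls
    for site ``j`` and SNP ``i``. ``n = 0`` encodes a fully missing cell."""

    site_ids: list[str]
    snp_ids: list[str]
    y: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        m, nn = self.y.shape
        if self.n.shape != (m, nn):
            raise CountsParseError("y and n matrices differ in shape")
        if m < 1:
            raise CountsParseError("need at least one site")
        # nn == 0 is permitted only as the result of filtering everything out
        if len(self.site_ids) != m or len(self.snp_ids) != nn:
            raise CountsParseError("id lists do not match matrix shape")
        if len(set(self.site_ids)) != m:
            raise CountsParseError("duplicate site id")
        if len(set(self.snp_ids)) != nn:
            raise CountsParseError("duplicate snp id")
        if (self.n < 0).any():
            j, i = np.argwhere(self.n < 0)[0]
            raise CountsParseError(f"negative n at site {self.site_ids[j]}, snp {self.snp_ids[i]}")
        if (self.y < 0).any():
            j, i = np.argwhere(self.y < 0)[0]
            raise CountsParseError(f"negative y at site {self.site_ids[j]}, snp {self.snp_ids[i]}")
        if (self.y > self.n).any():
            j, i = np.argwhere(self.y > self.n)[0]
            raise CountsParseError(
                f"y exceeds n at site {self.site_ids[j]}, snp {self.snp_ids[i]}"
            )

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_snps(self) -> int:
        return self.y.shape[1]


@dataclass
class SnpMeta:
    """Genomic positions of SNPs, used for sliding-window construction."""

    snp_ids: list[str]
    chrom: np.ndarray  # object array of chromosome labels
    pos: np.ndarray  # int base-pair positions

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos)):
            raise CountsParseError("SNP metadata columns differ in length")
        if (self.pos < 1).any():
            raise CountsParseError("SNP position must be >= 1")
        seen = set(zip(self.chrom.tolist(), self.pos.tolist()))
        if len(seen) != len(self.snp_ids):
            raise CountsParseError("duplicate (chrom, pos) in SNP metadata")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class SiteSet:
    """Sampling-site coordinates in decimal degrees."""

    site_ids: list[str]
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if len(set(self.site_ids)) != len(self.site_ids):
            raise CountsParseError("duplicate site id")
        if (np.abs(self.lat) > 90).any():
            raise CountsParseError("latitude outside [-90, 90]")
        if (np.abs(self.lon) > 180).any():
            raise CountsParseError("longitude outside [-180, 180]")

    def __len__(self) -> int:
        return len(self.site_ids)


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountsParseError(f"cannot parse {path}: {exc}") from exc


def read_counts(path) -> VariantCounts:
    """Read long-form pooled counts (columns ``site, snp, y, n``).

    Site and SNP order follow first appearance in the file. Cells absent from
    the file become ``n = 0, y = 0`` (fully missing).
    """
    df = _read_tsv(path)
    for col in ("site", "snp", "y", "n"):
        if col not in df.columns:
            raise CountsParseError(f"{path}: missing column '{col}'")
    for col in ("y", "n"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise CountsParseError(f"{path}: malformed number in column '{col}', row {row}") from exc
    if df.duplicated(subset=["site", "snp"]).any():
        d = df[df.duplicated(subset=["site", "snp"])].iloc[0]
        raise CountsParseError(f"{path}: duplicate row for site {d['site']}, snp {d['snp']}")
    site_ids = list(dict.fromkeys(df["site"]))
    snp_ids = list(dict.fromkeys(df["snp"]))
    jmap = {s: j for j, s in enumerate(site_ids)}
    imap = {s: i for i, s in enumerate(snp_ids)}
    y = np.zeros((len(site_ids), len(snp_ids)), dtype=np.int64)
    n = np.zeros_like(y)
    jj = df["site"].map(jmap).to_numpy()
    ii = df["snp"].map(imap).to_numpy()
    bad = df["y"].to_numpy() > df["n"].to_numpy()
    if bad.any():
        d = df[bad].iloc[0]
        raise CountsParseError(f"{path}: y exceeds n at site {d['site']}, snp {d['snp']}")
    y[jj, ii] = df["y"].to_numpy()
    n[jj, ii] = df["n"].to_numpy()
    return VariantCounts(site_ids, snp_ids, y, n)


def write_counts(counts: VariantCounts, path, header: str | None = None) -> None:
    """Write long-form counts; cells with ``n = 0`` are omitted."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("site\tsnp\ty\tn\n")
        for j, site in enumerate(counts.site_ids):
            for i, snp in enumerate(counts.snp_ids):
                if counts.n[j, i] > 0:
                    fh.write(f"{site}\t{snp}\t{counts.y[j, i]}\t{counts.n[j, i]}\n")


def read_sites(path) -> SiteSet:
    df = _read_tsv(path)
    for col in ("site", "lon", "lat"):
        if col not in df.columns:
            raise CountsParseError(f"{path}: missing column '{col}'")
    return SiteSet(list(df["site"]), df["lon"].astype(float).to_numpy(), df["lat"].astype(float).to_numpy())


def write_sites(sites: SiteSet, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("site\tlon\tlat\n")
        for s, lo, la in zip(sites.site_ids, sites.lon, sites.lat):
            fh.write(f"{s}\t{_FLOAT_FMT % lo}\t{_FLOAT_FMT % la}\n")


def read_snp_meta(path) -> SnpMeta:
    df = _read_tsv(path)
    for col in ("snp", "chrom", "pos"):
        if col not in df.columns:
            raise CountsParseError(f"{path}: missing column '{col}'")
    return SnpMeta(list(df["snp"]), df["chrom"].to_numpy(dtype=object), df["pos"].astype(np.int64).to_numpy())


def write_snp_meta(meta: SnpMeta, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("snp\tchrom\tpos\n")
        for s, c, p in zip(meta.snp_ids, meta.chrom, meta.pos):
            fh.write(f"{s}\t{c}\t{p}\n")


def write_frequencies(freqs: pd.DataFrame, path, header: str | None = None) -> None:
    """Write a population × SNP allele-frequency table.

    ``freqs`` has population labels as index and SNP ids as columns; every
    value must lie in [0, 1]. The written file round-trips bitwise through
    :func:`read_frequencies`.
    """
    vals = freqs.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any() or np.isnan(vals).any():
        r, c = np.argwhere((vals < 0) | (vals > 1) | np.isnan(vals))[0]
        raise CountsParseError(
            f"frequency outside [0,1] at pop {freqs.index[r]}, snp {freqs.columns[c]}"
        )
    _write_matrix(freqs, path, header)


def _write_matrix(df: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("pop\t" + "\t".join(str(c) for c in df.columns) + "\n")
        for idx, row in zip(df.index, df.to_numpy(dtype=float)):
            fh.write(str(idx) + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_frequencies(path) -> pd.DataFrame:
    """Read a population × SNP table written by :func:`write_frequencies`."""
    df = _read_tsv(path)
    if "pop" not in df.columns:
        raise CountsParseError(f"{path}: missing column 'pop'")
    df = df.set_index("pop")
    df.index.name = "pop"
    out = df.astype(float)
    if ((out.to_numpy() < 0) | (out.to_numpy() > 1)).any():
        raise CountsParseError(f"{path}: frequency outside [0,1]")
    return out


def read_balances(path) -> pd.DataFrame:
    """Read a population × SNP log-balance table (values unbounded)."""
    df = _read_tsv(path)
    if "pop" not in df.columns:
        raise CountsParseError(f"{path}: missing column 'pop'")
    return df.set_index("pop").astype(float)


def write_balances(bal: pd.DataFrame, path, header: str | None = None) -> None:
    _write_matrix(bal, path, header)


def filter_variants(
    counts: VariantCounts, maf_min: float = 0.03, callrate_min: float = 0.9
) -> VariantCounts:
    """Keep SNPs with pooled minor-allele frequency strictly above ``maf_min``
    and call-rate strictly above ``callrate_min``.

    Pooled MAF of SNP i is ``min(p, 1-p)`` with ``p = sum_j y[j,i] / sum_j
    n[j,i]``. Call-rate is approximated from pooled counts as ``sum_j n[j,i]``
    divided by the largest per-SNP total in the table (the per-accession
    denominator is not recoverable from pooled data).
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 < callrate_min <= 1):
        raise ValueError("callrate_min must be in (0, 1]")
    tot = counts.n.sum(axis=0).astype(float)
    alt = counts.y.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    maf = np.where(tot > 0, maf, 0.0)
    max_attainable = tot.max()
    callrate = tot / max_attainable if max_attainable > 0 else np.zeros_like(tot)
    keep = (maf > maf_min) & (callrate > callrate_min)
    if not keep.any():
        warnings.warn("all SNPs removed by variant filters", stacklevel=2)
    keep_idx = list(np.flatnonzero(keep))
    return VariantCounts(
        counts.site_ids,
        [counts.snp_ids[i] for i in keep_idx],
        counts.y[:, keep_idx],
        counts.n[:, keep_idx],
    )
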