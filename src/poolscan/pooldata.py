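"""Pooled SNP tables: reading, validation, filtering, and allele frequencies.

A :class:`SnpTable` holds one biallelic record per site with per-pool
reference/alternate read counts, the interchange object between a variant
caller upstream and the population-genetic estimators in this package.
Positions are 1-based (VCF convention) internally; BED exports are 0-based
half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

_SYNC_BASES = "ATCG"  # column order of the sync "A:T:C:G:N:del" field


@dataclass
class SnpTable:
    """Per-SNP, per-population read counts with site metadata.

    Parameters
    ----------
    sites : DataFrame with columns contig, pos, ref, alt, qual (pos 1-based).
    ref_counts, alt_counts : int arrays of shape (n_snps, n_pops).
    pools : DataFrame indexed by pool name with at least ``pool_diploids``;
        optional ``lat``/``long`` columns carry collection coordinates.
    """

    sites: pd.DataFrame
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    pools: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if self.ref_counts.shape != self.alt_counts.shape:
            raise ValueError("ref_counts and alt_counts shapes differ")
        if len(self.sites) != self.ref_counts.shape[0]:
            raise ValueError("sites and count matrices disagree on SNP count")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("negative read counts")
        self.sites = self.sites.reset_index(drop=True)
        for contig, grp in self.sites.groupby("contig", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on contig {contig}"
                )
        if self.pools.empty:
            npop = self.ref_counts.shape[1]
            self.pools = pd.DataFrame(
                {"pool_diploids": [100] * npop},
                index=[f"P{i + 1:02d}" for i in range(npop)],
            )

    @property
    def n_snps(self) -> int:
        return self.ref_counts.shape[0]

    @property
    def n_pops(self) -> int:
        return self.ref_counts.shape[1]

    @property
    def pool_names(self) -> list[str]:
        return list(self.pools.index)

    def depth(self) -> np.ndarray:
        """Total read depth per site per pool."""
        return self.ref_counts + self.alt_counts

    def select(self, mask: np.ndarray) -> "SnpTable":
        mask = np.asarray(mask)
        return SnpTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.ref_counts[mask],
            self.alt_counts[mask],
            self.pools.copy(),
        )

    # ------------------------------------------------------------------ I/O

    def to_sync(self, path: str) -> None:
        """Write a popoolation2 sync-style TSV (A:T:C:G:N:del counts)."""
        with open(path, "w") as fh:
            for i in range(self.n_snps):
                row = self.sites.iloc[i]
                counts = []
                for j in range(self.n_pops):
                    slots = {b: 0 for b in _SYNC_BASES}
                    slots[row.ref] = int(self.ref_counts[i, j])
                    if row.alt in slots:
                        slots[row.alt] = int(self.alt_counts[i, j])
                    counts.append(
                        ":".join(str(slots[b]) for b in _SYNC_BASES) + ":0:0"
                    )
                fh.write(
                    f"{row.contig}\t{row.pos}\t{row.ref}\t" + "\t".join(counts) + "\n"
                )

    def to_vcf(self, path: str, contig_lengths: dict[str, int] | None = None) -> None:
        """Write VCF 4.2 with per-pool AD genotype fields."""
        header = pysam.VariantHeader()
        contigs = list(dict.fromkeys(self.sites["contig"]))
        for c in contigs:
            length = (
                contig_lengths[c]
                if contig_lengths
                else int(self.sites.loc[self.sites.contig == c, "pos"].max()) + 1
            )
            header.contigs.add(c, length=length)
        header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
        for name in self.pool_names:
            header.add_sample(name)
        with pysam.VariantFile(path, "w", header=header) as vf:
            for i in range(self.n_snps):
                row = self.sites.iloc[i]
                rec = vf.new_record(
                    contig=row.contig,
                    start=int(row.pos) - 1,
                    stop=int(row.pos),
                    alleles=(row.ref, row.alt),
                    qual=float(row.qual) if np.isfinite(row.qual) else None,
                )
                for j, name in enumerate(self.pool_names):
                    rec.samples[name]["AD"] = (
                        int(self.ref_counts[i, j]),
                        int(self.alt_counts[i, j]),
                    )
                vf.write(rec)


class FilterResult(NamedTuple):
    """Filtered table plus counts of rows removed per criterion."""

    table: SnpTable
    n_removed_qual: int
    n_removed_cov: int


def read_snp_table(
    path: str,
    format: str = "vcf",
    pools: pd.DataFrame | None = None,
    default_qual: float = 60.0,
) -> SnpTable:
    """Read a pooled SNP table from VCF (AD or AO/RO fields) or sync TSV.

    Only biallelic SNPs are retained; multiallelic records are dropped and
    the dropped count logged. Sync rows carry no site quality, so
    ``default_qual`` is assigned (sync columns are mapped to ref/alt counts
    through the recorded reference base, with the alternate allele taken as
    the highest-count non-reference base across pools).
    """
    if format == "vcf":
        table = _read_vcf(path)
    elif format == "sync":
        table = _read_sync(path, default_qual)
    else:
        raise ValueError(f"unknown format {format!r}")
    if pools is not None:
        if len(pools) != table.n_pops:
            raise ValueError("pool metadata does not match column count")
        table.pools = pools.copy()
    return table


def _read_vcf(path: str) -> SnpTable:
    rows, refs, alts = [], [], []
    n_multi = 0
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        header_contigs = set(vf.header.contigs)
        for rec in vf:
            if header_contigs and rec.contig not in header_contigs:
                raise ValueError(f"contig {rec.contig} absent from VCF header")
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            ref_c, alt_c = [], []
            for s in samples:
                sm = rec.samples[s]
                if "AD" in sm and sm["AD"] is not None and sm["AD"][0] is not None:
                    ad = sm["AD"]
                    ref_c.append(int(ad[0]))
                    alt_c.append(int(ad[1]))
                elif "RO" in sm and "AO" in sm:
                    ref_c.append(int(sm["RO"]))
                    ao = sm["AO"]
                    alt_c.append(int(ao[0] if isinstance(ao, tuple) else ao))
                else:
                    raise ValueError(
                        f"no AD or AO/RO counts for sample {s} at "
                        f"{rec.contig}:{rec.pos}"
                    )
            rows.append(
                {
                    "contig": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "qual": rec.qual if rec.qual is not None else np.nan,
                }
            )
            refs.append(ref_c)
            alts.append(alt_c)
    if n_multi:
        log.info("dropped %d multiallelic records", n_multi)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "qual"])
    npop = len(samples)
    pools = pd.DataFrame({"pool_diploids": [100] * npop}, index=samples)
    return SnpTable(
        sites,
        np.array(refs, dtype=np.int64).reshape(len(rows), npop),
        np.array(alts, dtype=np.int64).reshape(len(rows), npop),
        pools,
    )


def _read_sync(path: str, default_qual: float) -> SnpTable:
    rows, refs, alts = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed sync line {lineno}: too few columns")
            contig, pos_s, ref = parts[0], parts[1], parts[2].upper()
            try:
                pos = int(pos_s)
                counts = np.array(
                    [[int(x) for x in col.split(":")] for col in parts[3:]],
                    dtype=np.int64,
                )
            except ValueError as exc:
                raise ValueError(f"malformed sync line {lineno}: {exc}") from exc
            if counts.shape[1] < 4:
                raise ValueError(f"malformed sync line {lineno}: short count field")
            if ref not in _SYNC_BASES:
                raise ValueError(f"malformed sync line {lineno}: ref base {ref!r}")
            base_tot = counts[:, :4].sum(axis=0)
            ref_idx = _SYNC_BASES.index(ref)
            nonref = [i for i in range(4) if i != ref_idx]
            alt_idx = max(nonref, key=lambda i: base_tot[i])
            alt = _SYNC_BASES[alt_idx] if base_tot[alt_idx] > 0 else "."
            rows.append(
                {"contig": contig, "pos": pos, "ref": ref, "alt": alt,
                 "qual": default_qual}
            )
            refs.append(counts[:, ref_idx])
            alts.append(counts[:, alt_idx])
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "qual"])
    return SnpTable(sites, np.array(refs), np.array(alts))


def filter_snps(
    table: SnpTable, min_qual: float = 30.0, min_cov: int = 10
) -> FilterResult:
    """Retain SNPs with site quality >= ``min_qual`` and read depth >=
    ``min_cov`` in *every* pool.

    Returns the filtered table together with the number of rows removed by
    each criterion (a row failing both is charged to the quality criterion).
    Filtering is idempotent.
    """
    if min_qual < 0 or min_cov < 0:
        raise ValueError("thresholds must be non-negative")
    qual_ok = table.sites["qual"].to_numpy() >= min_qual
    cov_ok = (table.depth() >= min_cov).all(axis=1)
    keep = qual_ok & cov_ok
    n_qual = int((~qual_ok).sum())
    n_cov = int((qual_ok & ~cov_ok).sum())
    if not keep.any():
        warnings.warn("all SNPs removed by filtering", stacklevel=2)
    log.info(
        "filter_snps: %d removed by qual<%s, %d by cov<%s in any pool, %d kept",
        n_qual, min_qual, n_cov, min_cov, int(keep.sum()),
    )
    return FilterResult(table.select(keep), n_qual, n_cov)


def allele_freqs(table: SnpTable) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency and depth matrices, shape (n_snps, n_pops).

    Requires every site to have positive depth in every pool (guaranteed
    after :func:`filter_snps` with ``min_cov >= 1``).
    """
    depth = table.depth()
    assert (depth > 0).all(), "zero-depth site; filter before computing freqs"
    return table.alt_counts / depth, depth


def folded_sfs(freqs: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Folded (minor-allele frequency) spectrum per population.

    Returns an (n_bins, n_pops) histogram over [0, 0.5]; columns sum to the
    SNP count.
    """
    freqs = np.asarray(freqs)
    if freqs.ndim == 1:
        freqs = freqs[:, None]
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies outside [0,1]")
    maf = np.minimum(freqs, 1.0 - freqs)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    out = np.empty((n_bins, maf.shape[1]), dtype=np.int64)
    for j in range(maf.shape[1]):
        out[:, j], _ = np.histogram(maf[:, j], bins=edges)
    return out
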