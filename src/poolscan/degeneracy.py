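"""4-fold degenerate site ascertainment from FASTA + GFF3.

A genomic site qualifies as 4-fold degenerate only if, for *every*
transcript whose CDS covers it, the site falls on the third position of a
codon whose encoded amino acid is invariant to all four bases. Sites in the
phase-trimmed leading bases of a CDS are covered but can never qualify.
Transcripts whose assembled CDS is not divisible by three after phase
adjustment are excluded from both the covering and the qualifying role
(conservative: their sites simply never block or contribute). The resulting
site set is the putatively neutral class used for population-covariance
estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

__all__ = ["DegenerateSiteSet", "fourfold_sites", "fourfold_prefixes"]


def fourfold_prefixes(table_id: int = 1) -> frozenset[str]:
    """Codon prefixes (first two bases) whose third position is 4-fold.

    Computed from the genetic code table (standard code by default).
    """
    table = unambiguous_dna_by_id[table_id]

    def aa(codon: str) -> str:
        return table.forward_table.get(codon, "*")

    out = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {aa(b1 + b2 + b3) for b3 in "ACGT"}
            if len(aas) == 1 and "*" not in aas:
                out.add(b1 + b2)
    return frozenset(out)


@dataclass
class DegenerateSiteSet:
    """Sorted 1-based 4-fold site positions per contig, with provenance."""

    sites: dict[str, np.ndarray]
    provenance: dict[tuple[str, int], tuple[str, ...]] = field(
        default_factory=dict
    )

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def contains(self, contig: str, pos: int) -> bool:
        arr = self.sites.get(contig)
        if arr is None:
            return False
        i = np.searchsorted(arr, pos)
        return i < len(arr) and arr[i] == pos

    def mask(self, contigs, positions) -> np.ndarray:
        """Boolean mask over (contig, pos) pairs that are 4-fold sites."""
        out = np.zeros(len(positions), dtype=bool)
        contigs = np.asarray(contigs)
        positions = np.asarray(positions)
        for contig, arr in self.sites.items():
            sel = contigs == contig
            idx = np.searchsorted(arr, positions[sel])
            hit = (idx < len(arr)) & (arr[np.minimum(idx, len(arr) - 1)]
                                      == positions[sel])
            out[np.flatnonzero(sel)[hit]] = True
        return out

    def to_bed(self, path: str) -> None:
        """Write sites as 0-based half-open BED."""
        with open(path, "w") as fh:
            for contig in sorted(self.sites):
                for p in self.sites[contig]:
                    fh.write(f"{contig}\t{p - 1}\t{p}\n")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _transcript_codons(db, mrna, genome):
    """Yield (codon, (g0, g1, g2)) genomic coordinates in transcription order.

    Returns None if the phase-adjusted CDS length is not divisible by 3.
    Also returns the full list of genomically covered positions.
    """
    cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
    if not cds:
        return None, []
    strand = cds[0].strand
    covered = []
    coords: list[int] = []
    bases: list[str] = []
    if strand == "+":
        ordered = cds
    else:
        ordered = list(reversed(cds))
    seq = genome[mrna.seqid]
    for f in ordered:
        span = range(f.start, f.end + 1)
        covered.extend(span)
        if strand == "+":
            for p in span:
                coords.append(p)
                bases.append(seq[p - 1])
        else:
            for p in reversed(span):
                coords.append(p)
                bases.append(seq[p - 1].translate(_COMPLEMENT))
    first = ordered[0]
    phase = int(first.frame) if first.frame not in (".", None) else 0
    coords = coords[phase:]
    bases = bases[phase:]
    if len(coords) % 3 != 0:
        return None, covered
    codons = [
        ("".join(bases[k : k + 3]), tuple(coords[k : k + 3]))
        for k in range(0, len(coords), 3)
    ]
    return codons, covered


def fourfold_sites(
    fasta_path: str, gff_path: str, codon_table: int = 1
) -> DegenerateSiteSet:
    """Identify genomic sites 4-fold degenerate in all covering transcripts."""
    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(fasta_path, "fasta")
    }
    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    prefixes = fourfold_prefixes(codon_table)

    covering: dict[tuple[str, int], set[str]] = {}
    qualifying: dict[tuple[str, int], set[str]] = {}
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        codons, covered = _transcript_codons(db, mrna, genome)
        if codons is None:
            warnings.warn(
                f"transcript {tid}: CDS length not divisible by 3 after "
                "phase adjustment; transcript excluded",
                stacklevel=2,
            )
            continue
        for p in covered:
            covering.setdefault((mrna.seqid, p), set()).add(tid)
        for codon, (g0, g1, g2) in codons:
            if codon[:2] in prefixes:
                qualifying.setdefault((mrna.seqid, g2), set()).add(tid)

    per_contig: dict[str, list[int]] = {}
    provenance: dict[tuple[str, int], tuple[str, ...]] = {}
    for key, cov in covering.items():
        if qualifying.get(key) == cov:
            contig, pos = key
            per_contig.setdefault(contig, []).append(pos)
            provenance[key] = tuple(sorted(cov))
    sites = {
        c: np.array(sorted(ps), dtype=np.int64) for c, ps in per_contig.items()
    }
    return DegenerateSiteSet(sites, provenance)


def translate(seq: str) -> str:
    """Translate a CDS (helper for oracle-style checks)."""
    return str(Seq(seq).translate())
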