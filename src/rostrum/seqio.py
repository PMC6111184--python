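"""Alignment I/O and SNP-matrix construction.

The analyses downstream all consume a :class:`SnpMatrix` built from a
multi-sequence mitogenome alignment with one designated outgroup record.
Coordinates are 1-based alignment columns throughout, matching the
reference positions used for the control-region markers (e.g. 15564).

Genotype-level quality filtering happens upstream of this package (on read
data we do not model); here 'N' characters stand in for genotypes that such
a filter set to missing, and alignment columns containing gaps are excluded
entirely, mirroring indel exclusion in the original variant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

MISSING = -1
_VALID_BASES = frozenset("ACGTN-")


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass
class SpecimenAlignment:
    """Aligned specimen sequences plus one outgroup record.

    ``records`` is an ordered list of ``(id, sequence)`` pairs; sequences may
    contain 'N' (missing) and '-' (gap). Position k means alignment column k,
    1-based.
    """

    records: list[tuple[str, str]]
    outgroup_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise FormatError(f"duplicate record ids: {sorted(dupes)}")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.outgroup_id not in ids:
            raise FormatError(f"outgroup id {self.outgroup_id!r} not among records")
        for rid, seq in self.records:
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(f"record {rid!r} has invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def ingroup_ids(self) -> list[str]:
        return [rid for rid, _ in self.records if rid != self.outgroup_id]

    def sequence(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)


@dataclass
class SnpMatrix:
    """Specimens x variable-sites genotype matrix.

    ``genotypes[i, j]`` is an index into ``alleles[j]`` or :data:`MISSING`.
    ``positions`` are strictly increasing 1-based alignment columns.  The
    outgroup genotype is carried separately and never defines polymorphism.
    """

    positions: np.ndarray
    alleles: list[list[str]]
    genotypes: np.ndarray
    specimen_ids: list[str]
    outgroup_id: str
    outgroup_row: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.genotypes.shape != (len(self.specimen_ids), len(self.positions)):
            raise ValueError("genotype matrix shape mismatch")
        for j, al in enumerate(self.alleles):
            col = self.genotypes[:, j]
            if col[col != MISSING].size and col.max() >= len(al):
                raise ValueError(f"genotype index out of range at site {j}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    def site_bases(self, j: int) -> list[str | None]:
        """Per-specimen base at site j (None when missing)."""
        return [
            self.alleles[j][g] if g != MISSING else None for g in self.genotypes[:, j]
        ]

    def restrict_alignment(self) -> SpecimenAlignment:
        """Re-materialize an alignment restricted to the retained sites."""
        cols = {}
        for i, rid in enumerate(self.specimen_ids):
            cols[rid] = "".join(
                self.alleles[j][g] if g != MISSING else "N"
                for j, g in enumerate(self.genotypes[i])
            )
        cols[self.outgroup_id] = "".join(
            self.alleles[j][g] if g != MISSING else "N"
            for j, g in enumerate(self.outgroup_row)
        )
        return SpecimenAlignment(
            records=[(rid, cols[rid]) for rid in self.specimen_ids + [self.outgroup_id]],
            outgroup_id=self.outgroup_id,
        )


def read_fasta(path, outgroup_id: str) -> SpecimenAlignment:
    """Read an aligned FASTA; sequences are upper-cased on read."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return SpecimenAlignment(records=records, outgroup_id=outgroup_id)


def write_fasta(aln: SpecimenAlignment, path) -> None:
    """Write the alignment as FASTA wrapped at 70 columns."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(recs)


def call_snps(
    aln: SpecimenAlignment, max_missing_fraction: float = 0.5, log=None
) -> SnpMatrix:
    """Extract variable sites from the alignment into a :class:`SnpMatrix`.

    Filtering rules, applied per alignment column:

    1. columns containing '-' in any record are dropped (indel exclusion);
    2. columns whose ingroup missing ('N') fraction exceeds
       ``max_missing_fraction`` are dropped;
    3. columns monomorphic among non-missing ingroup genotypes are dropped —
       the outgroup never defines polymorphism.

    Allele order per retained site: ingroup major allele first, then by
    descending count (ties alphabetical).
    """
    ingroup = aln.ingroup_ids
    if not ingroup:
        raise ValueError("alignment has no ingroup records")
    arr = np.array([list(seq) for _, seq in aln.records])
    idx = {rid: i for i, (rid, _) in enumerate(aln.records)}
    ing_rows = [idx[r] for r in ingroup]
    out_row = idx[aln.outgroup_id]

    n_gap = n_miss = n_mono = 0
    positions, alleles, geno_cols, out_vals = [], [], [], []
    for col in range(arr.shape[1]):
        column = arr[:, col]
        if "-" in column:
            n_gap += 1
            continue
        ing = column[ing_rows]
        missing = ing == "N"
        if missing.mean() > max_missing_fraction:
            n_miss += 1
            continue
        obs = ing[~missing]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) < 2:
            n_mono += 1
            continue
        order = sorted(range(len(uniq)), key=lambda k: (-counts[k], uniq[k]))
        site_alleles = [str(uniq[k]) for k in order]
        amap = {a: i for i, a in enumerate(site_alleles)}
        geno_cols.append([MISSING if b == "N" else amap[b] for b in ing])
        og = str(column[out_row])
        if og == "N":
            out_vals.append(MISSING)
        else:
            if og not in amap:
                amap[og] = len(site_alleles)
                site_alleles.append(og)
            out_vals.append(amap[og])
        positions.append(col + 1)
        alleles.append(site_alleles)

    if log is not None:
        log.info("call_snps: dropped %d gap columns", n_gap)
        log.info(
            "call_snps: dropped %d columns over missing fraction %.3g",
            n_miss, max_missing_fraction,
        )
        log.info("call_snps: dropped %d monomorphic columns", n_mono)
        log.info("call_snps: retained %d variable sites", len(positions))

    genotypes = (
        np.array(geno_cols, dtype=int).T
        if geno_cols
        else np.empty((len(ingroup), 0), dtype=int)
    )
    return SnpMatrix(
        positions=np.array(positions, dtype=int),
        alleles=alleles,
        genotypes=genotypes,
        specimen_ids=list(ingroup),
        outgroup_id=aln.outgroup_id,
        outgroup_row=np.array(out_vals, dtype=int),
    )


def write_variant_table(m: SnpMatrix, path) -> None:
    """Write a VCF-like TSV: POS, REF, ALT, then one genotype column per specimen.

    REF is the outgroup allele when non-missing, else the ingroup major
    allele; genotypes are allele indices, '.' for missing.
    """
    with open(path, "w") as fh:
        fh.write("POS\tREF\tALT\t" + "\t".join(m.specimen_ids) + "\n")
        for j in range(m.n_sites):
            al = m.alleles[j]
            og = m.outgroup_row[j]
            ref = al[og] if og != MISSING else al[0]
            alt = ",".join(a for a in al if a != ref)
            row = [
                "." if g == MISSING else str(g) for g in m.genotypes[:, j]
            ]
            fh.write(f"{m.positions[j]}\t{ref}\t{alt}\t" + "\t".join(row) + "\n")


def read_variant_table(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read back a table written by :func:`write_variant_table`.

    Returns ``(positions, specimen_ids, genotypes)``; allele identity beyond
    index is not recoverable from the table alone.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = header[3:]
        positions, rows = [], []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            positions.append(int(f[0]))
            rows.append([MISSING if g == "." else int(g) for g in f[3:]])
    geno = (
        np.array(rows, dtype=int).T if rows else np.empty((len(ids), 0), dtype=int)
    )
    return np.array(positions, dtype=int), ids, geno
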