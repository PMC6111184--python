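"""Legacy marker reinterpretation: RFLP motifs and control-region haplotypes.

Historical population assignments for Atlantic walrus rested on two partial
mitochondrial marker systems: restriction-fragment (RFLP) patterns and short
control-region (CR) haplotypes.  Full mitogenome clades explain both — a
clade-diagnostic SNP can create or destroy an enzyme recognition site, and
the CR haplotype defined by positions 15564/15760/15779 (the "ACC"
haplotype) tracks the western clade in population data.  This module scans
IUPAC-degenerate recognition motifs, reports which diagnostic SNPs disrupt
them, classifies CR genotypes, and tabulates haplotype frequencies by
region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import SpecimenRecord

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class EnzymeMotif:
    name: str
    recognition: str
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition motif")
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters in motif: {sorted(bad)}")

    @property
    def reverse_complement(self) -> str:
        return self.recognition.upper().translate(_COMPLEMENT)[::-1]


# A documented default panel of common restriction enzymes; overridable via
# a motif config TSV.  The original RFLP surveys' exact panel is not part of
# this package's inputs — the scan operation is generic over any panel.
DEFAULT_ENZYME_PANEL = (
    EnzymeMotif("EcoRI", "GAATTC"),
    EnzymeMotif("BamHI", "GGATCC"),
    EnzymeMotif("HindIII", "AAGCTT"),
    EnzymeMotif("PstI", "CTGCAG"),
    EnzymeMotif("EcoRV", "GATATC"),
    EnzymeMotif("DraI", "TTTAAA"),
    EnzymeMotif("XbaI", "TCTAGA"),
    EnzymeMotif("HincII", "GTYRAC"),
    EnzymeMotif("AvaI", "CYCGRG"),
    EnzymeMotif("HinfI", "GANTC"),
)


@dataclass
class SiteChange:
    enzyme: str
    snp_position: int
    allele_west: str
    allele_east: str
    effect: str                      # "created" | "destroyed" | "none"
    direction: str                   # clade whose allele carries the site, or ""
    motif_window: tuple[int, int]    # 1-based inclusive
    gene_region: str | None = None

    def __post_init__(self) -> None:
        if self.effect not in ("created", "destroyed", "none"):
            raise ValueError(f"bad effect {self.effect!r}")
        if self.effect != "none":
            lo, hi = self.motif_window
            if not lo <= self.snp_position <= hi:
                raise ValueError("SNP outside its motif window")


@dataclass
class HaplotypeDefinition:
    """Scored CR positions and the target (western-clade) haplotype."""

    positions: tuple[int, ...] = (15564, 15760, 15779)
    target: str = "ACC"
    window: tuple[int, int] = (15328, 15827)

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        if len(self.target) != len(self.positions):
            raise ValueError("target length must match number of positions")
        lo, hi = self.window
        if not all(lo <= p <= hi for p in self.positions):
            raise ValueError("positions must lie inside the context window")


@dataclass
class RegionTable:
    """Per-region counts of the target haplotype among determined calls."""

    rows: dict[str, tuple[int, int, float]]          # region -> (n_total, n_target, freq)
    undetermined: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "region": r, "n_total": t, "n_target": k, "frequency": f,
                "n_undetermined": self.undetermined.get(r, 0),
            }
            for r, (t, k, f) in sorted(self.rows.items())
        ]
        return pd.DataFrame(
            recs, columns=["region", "n_total", "n_target", "frequency", "n_undetermined"]
        )


def scan_motif(seq: str, motif: EnzymeMotif) -> list[tuple[int, str]]:
    """All 1-based start positions where the motif matches, with strand.

    Reverse-strand hits are reported against forward coordinates (the start
    of the matching window on the forward sequence).  'N' in the subject
    never matches any code, so missing data cannot fabricate a site.  When a
    palindromic motif hits the same window on both strands only the forward
    hit is kept.
    """
    seq = seq.upper()
    patterns = [(motif.recognition.upper(), "+")]
    if motif.scan_both_strands:
        rc = motif.reverse_complement
        if rc != motif.recognition.upper():
            patterns.append((rc, "-"))
    hits = []
    k = len(motif.recognition)
    for pat, strand in patterns:
        sets = [IUPAC[c] for c in pat]
        for start in range(len(seq) - k + 1):
            window = seq[start : start + k]
            if all(b in s for b, s in zip(window, sets)):
                hits.append((start + 1, strand))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _hits_in_window(seq: str, motif: EnzymeMotif, lo: int, hi: int) -> set[int]:
    """Motif hit starts (1-based, strand-collapsed) intersecting [lo, hi]."""
    k = len(motif.recognition)
    a = max(lo - k, 0)
    sub = seq[a : hi + k]
    return {a + p for p, _ in scan_motif(sub, motif)}


def site_changes(
    ref: str,
    diagnostic: list[tuple[int, str, str]],
    motifs: list[EnzymeMotif] | tuple[EnzymeMotif, ...] = DEFAULT_ENZYME_PANEL,
    gene_regions: list[tuple[int, int, str]] | None = None,
) -> list[SiteChange]:
    """Which diagnostic SNPs create or destroy enzyme recognition sites.

    For each SNP ``(pos, allele_west, allele_east)`` and each motif, the
    window ``[pos - |motif| + 1, pos + |motif| - 1]`` is rescanned with each
    clade allele substituted into the reference.  ``effect`` is "created"
    (with ``direction`` naming the clade whose allele carries the site) when
    a hit overlapping the SNP exists under exactly one allele; "none" when
    the hit sets are identical.  ``gene_regions`` optionally labels SNPs with
    user-supplied position intervals (e.g. ND1/ND2/ND3-4).
    """
    ref = ref.upper()
    out: list[SiteChange] = []
    for pos, a_w, a_e in diagnostic:
        if not 1 <= pos <= len(ref):
            raise ValueError(f"SNP position {pos} outside reference")
        if len(a_w) != 1 or len(a_e) != 1:
            raise ValueError("clade alleles must be single bases")
        if a_w == a_e and ref[pos - 1] == a_w:
            raise ValueError(f"position {pos} is not variable between clades")
        label = None
        if gene_regions:
            for lo, hi, name in gene_regions:
                if lo <= pos <= hi:
                    label = name
                    break
        for motif in motifs:
            k = len(motif.recognition)
            lo, hi = max(1, pos - k + 1), min(len(ref), pos + k - 1)
            variants = {}
            for clade, allele in (("western", a_w), ("eastern", a_e)):
                var = ref[: pos - 1] + allele + ref[pos:]
                variants[clade] = {
                    h for h in _hits_in_window(var, motif, lo, hi)
                    if h <= pos <= h + k - 1
                }
            only_w = variants["western"] - variants["eastern"]
            only_e = variants["eastern"] - variants["western"]
            if not only_w and not only_e:
                out.append(SiteChange(
                    enzyme=motif.name, snp_position=pos, allele_west=a_w,
                    allele_east=a_e, effect="none", direction="",
                    motif_window=(lo, hi), gene_region=label,
                ))
                continue
            for clade, extra in (("western", only_w), ("eastern", only_e)):
                for h in sorted(extra):
                    out.append(SiteChange(
                        enzyme=motif.name, snp_position=pos, allele_west=a_w,
                        allele_east=a_e, effect="created", direction=clade,
                        motif_window=(h, h + k - 1), gene_region=label,
                    ))
    return out


def classify_cr(
    genotypes, hapdef: HaplotypeDefinition = HaplotypeDefinition()
) -> tuple[str, bool | None]:
    """Concatenate the scored bases into a haplotype string and test it.

    Any missing genotype (None, '', 'N', '?') makes the call UNDETERMINED
    (``is_target`` None) rather than silently non-target.
    """
    genotypes = list(genotypes)
    if len(genotypes) != len(hapdef.positions):
        raise ValueError(
            f"expected {len(hapdef.positions)} genotypes, got {len(genotypes)}"
        )
    bases = []
    missing = False
    for g in genotypes:
        if g is None or str(g).upper() in ("", "N", "?", "NAN"):
            bases.append("?")
            missing = True
        else:
            bases.append(str(g).upper())
    hap = "".join(bases)
    if missing:
        return hap, None
    return hap, hap == hapdef.target


def tabulate_by_region(
    calls: dict[str, bool | None], metadata: dict[str, str] | list[SpecimenRecord]
) -> RegionTable:
    """Count target-haplotype carriers per region.

    ``calls`` maps individual id -> is_target (None = UNDETERMINED, excluded
    from numerator and denominator, reported separately).  ``metadata`` maps
    id -> region (a SpecimenRecord list is accepted too).
    """
    if not isinstance(metadata, dict):
        metadata = {r.id: r.region for r in metadata}
    totals: dict[str, int] = {}
    targets: dict[str, int] = {}
    undet: dict[str, int] = {}
    for rid, call in calls.items():
        if rid not in metadata:
            raise ValueError(f"no region metadata for id {rid!r}")
        region = metadata[rid]
        if call is None:
            undet[region] = undet.get(region, 0) + 1
            continue
        totals[region] = totals.get(region, 0) + 1
        if call:
            targets[region] = targets.get(region, 0) + 1
    rows = {
        r: (n, targets.get(r, 0), targets.get(r, 0) / n) for r, n in totals.items()
    }
    for r in undet:
        rows.setdefault(r, (0, 0, 0.0))
    return RegionTable(rows=rows, undetermined=undet)


def read_motif_panel(path) -> list[EnzymeMotif]:
    """Read a motif config TSV with columns ``enzyme`` and ``recognition``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [EnzymeMotif(r["enzyme"], r["recognition"]) for _, r in df.iterrows()]


def write_site_changes(changes: list[SiteChange], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "enzyme\tpos\tallele_west\tallele_east\teffect\tdirection\t"
            "window_start\twindow_end\tgene_region\n"
        )
        for c in changes:
            fh.write(
                f"{c.enzyme}\t{c.snp_position}\t{c.allele_west}\t{c.allele_east}\t"
                f"{c.effect}\t{c.direction}\t{c.motif_window[0]}\t{c.motif_window[1]}\t"
                f"{c.gene_region or ''}\n"
            )
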