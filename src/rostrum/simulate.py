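"""Synthetic mitogenome, metadata and control-region data generation.

The generator emulates the statistical structure the analyses assume:

* two monophyletic mitochondrial clades ("western" / "eastern") separated by
  clade-diagnostic fixed SNPs on a ~16.5 kb reference, plus within-clade
  private polymorphism and a divergent outgroup;
* dated specimens whose clade composition differs before/after 1125 CE
  (defaults reproduce the 1 western : 6 eastern vs 10 western : 2 eastern
  archaeological counts);
* regional control-region haplotype frequencies with the ACC haplotype fixed
  in Northwest Greenland, absent from the Northeast Atlantic, and at
  intermediate frequency in West Greenland / Canada.

All randomness flows through one numpy Generator per call, seeded from the
config, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import SpecimenAlignment

BASES = np.array(list("ACGT"))

REGIONS = (
    "NW_Greenland",
    "W_Greenland",
    "Canada",
    "NE_Atlantic",
    "Europe_find",
    "Svalbard",
    "Greenland_find",
)

CR_POSITIONS = (15564, 15760, 15779)
ACC = "ACC"
# Non-ACC haplotypes observed in the population data are not enumerated in
# the source marker set; any fixed alternative alphabet serves classification.
ALT_HAPLOTYPES = ("GCC", "ACT", "GCT")


@dataclass
class SimConfig:
    """Parameters of the two-clade alignment simulation.

    ``n_diagnostic`` sites are fixed differences between the clades;
    ``n_private_per_clade`` sites are polymorphic within exactly one clade;
    the outgroup differs from the ingroup consensus at ``outgroup_divergence``
    additional sites.  ``miscall_rate`` substitutes a uniformly random other
    base per ingroup base; ``missing_rate`` masks ingroup genotypes to 'N'.
    """

    genome_length: int = 16565
    n_west: int = 11
    n_east: int = 8
    n_diagnostic: int = 39
    n_private_per_clade: int = 20
    outgroup_divergence: int = 250
    miscall_rate: float = 0.001
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.genome_length, self.n_west, self.n_east, self.n_diagnostic,
            self.n_private_per_clade, self.outgroup_divergence,
        )
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError("counts must be nonnegative integers")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        budget = self.n_diagnostic + 2 * self.n_private_per_clade + self.outgroup_divergence
        if budget > self.genome_length:
            raise ValueError(
                f"site budget {budget} exceeds genome length {self.genome_length}"
            )
        for name in ("miscall_rate", "missing_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SpecimenRecord:
    id: str
    location: str
    region: str
    date_lo: int
    date_hi: int
    true_clade: str = "unknown"

    def __post_init__(self) -> None:
        if self.date_lo > self.date_hi:
            raise ValueError(f"{self.id}: date_lo > date_hi")
        if self.region not in REGIONS:
            raise ValueError(f"{self.id}: unknown region {self.region!r}")

    @property
    def midpoint(self) -> float:
        return (self.date_lo + self.date_hi) / 2.0


@dataclass
class CrPopConfig:
    """Sizes and ACC-haplotype frequencies per sampled region."""

    region_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "NW_Greenland": 30, "W_Greenland": 120, "Canada": 60, "NE_Atlantic": 96,
        }
    )
    acc_frequency: dict[str, float] = field(
        default_factory=lambda: {
            "NW_Greenland": 1.0, "W_Greenland": 0.124, "Canada": 0.15, "NE_Atlantic": 0.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for r in list(self.region_sizes) + list(self.acc_frequency):
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}")
        for r, f in self.acc_frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"acc_frequency[{r!r}] outside [0, 1]")
        for r in self.region_sizes:
            if r not in self.acc_frequency:
                raise ValueError(f"no acc_frequency for region {r!r}")


@dataclass
class SiteTruth:
    """Ground truth recorded before noise is applied."""

    diagnostic_positions: list[int]
    derived_clade: dict[int, str]          # diagnostic position -> clade carrying alt
    private_positions: dict[str, list[int]]
    outgroup_positions: list[int]
    clade_alleles: dict[int, tuple[str, str]]  # position -> (allele_west, allele_east)


def simulate_reference(length: int, seed: int) -> str:
    """Uniform-random nucleotide sequence of the given length."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(BASES, size=length))


def _nested_subsets(members: list[str], rng: np.random.Generator) -> list[tuple[str, ...]]:
    """Proper non-empty leaf sets of a random bifurcating genealogy over
    ``members``: singletons plus every internal cluster except the full set."""
    clusters = [(m,) for m in members]
    pool = list(clusters)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        if len(merged) < len(members):
            pool.append(merged)
    return pool


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def simulate_two_clade_alignment(
    cfg: SimConfig,
) -> tuple[SpecimenAlignment, dict[str, str], SiteTruth]:
    """Simulate the two-clade alignment plus its truth tables.

    Returns ``(alignment, true_clade_by_id, site_truth)``.  Specimen ids are
    ``W01..`` / ``E01..`` with outgroup ``OUTGROUP``.  Each diagnostic site's
    derived allele is placed on a uniformly random clade, so the fixed
    differences split across both clade stems; their total is exactly
    ``cfg.n_diagnostic``.  Noise is applied to ingroup records only, after
    truth is recorded.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = np.array(list(simulate_reference(cfg.genome_length, cfg.seed)))

    n_sites = cfg.n_diagnostic + 2 * cfg.n_private_per_clade + cfg.outgroup_divergence
    chosen = rng.choice(cfg.genome_length, size=n_sites, replace=False)
    pos_diag = np.sort(chosen[: cfg.n_diagnostic]) + 1
    k = cfg.n_diagnostic
    pos_priv_w = np.sort(chosen[k : k + cfg.n_private_per_clade]) + 1
    k += cfg.n_private_per_clade
    pos_priv_e = np.sort(chosen[k : k + cfg.n_private_per_clade]) + 1
    k += cfg.n_private_per_clade
    pos_out = np.sort(chosen[k:]) + 1

    west_ids = [f"W{i + 1:02d}" for i in range(cfg.n_west)]
    east_ids = [f"E{i + 1:02d}" for i in range(cfg.n_east)]
    seqs = {rid: ref.copy() for rid in west_ids + east_ids}

    derived_clade: dict[int, str] = {}
    clade_alleles: dict[int, tuple[str, str]] = {}
    for p in pos_diag:
        refb = str(ref[p - 1])
        alt = _other_base(rng, refb)
        clade = "western" if rng.random() < 0.5 else "eastern"
        derived_clade[int(p)] = clade
        carriers = west_ids if clade == "western" else east_ids
        for rid in carriers:
            seqs[rid][p - 1] = alt
        clade_alleles[int(p)] = (alt, refb) if clade == "western" else (refb, alt)

    # private sites: derived allele carried by a proper, non-empty subset of
    # one clade, so the site is polymorphic within that clade only.  mtDNA is
    # clonal, so carrier sets are drawn from one random within-clade
    # genealogy (nested subsets): every variant has a single origin and all
    # sites are compatible with one tree.
    for positions, members in ((pos_priv_w, west_ids), (pos_priv_e, east_ids)):
        if len(members) < 2:
            continue
        carriers_pool = _nested_subsets(members, rng)
        for p in positions:
            refb = str(ref[p - 1])
            alt = _other_base(rng, refb)
            carriers = carriers_pool[rng.integers(len(carriers_pool))]
            for rid in carriers:
                seqs[rid][p - 1] = alt

    outseq = ref.copy()
    for p in pos_out:
        outseq[p - 1] = _other_base(rng, str(ref[p - 1]))

    truth_clade = {rid: "western" for rid in west_ids}
    truth_clade.update({rid: "eastern" for rid in east_ids})
    site_truth = SiteTruth(
        diagnostic_positions=[int(p) for p in pos_diag],
        derived_clade=derived_clade,
        private_positions={
            "western": [int(p) for p in pos_priv_w],
            "eastern": [int(p) for p in pos_priv_e],
        },
        outgroup_positions=[int(p) for p in pos_out],
        clade_alleles=clade_alleles,
    )

    # noise after truth: miscalls then missingness, ingroup only
    for rid in west_ids + east_ids:
        s = seqs[rid]
        if cfg.miscall_rate > 0:
            hit = rng.random(cfg.genome_length) < cfg.miscall_rate
            for i in np.flatnonzero(hit):
                s[i] = _other_base(rng, str(s[i]))
        if cfg.missing_rate > 0:
            s[rng.random(cfg.genome_length) < cfg.missing_rate] = "N"

    records = [(rid, "".join(seqs[rid])) for rid in west_ids + east_ids]
    records.append(("OUTGROUP", "".join(outseq)))
    aln = SpecimenAlignment(records=records, outgroup_id="OUTGROUP")
    return aln, truth_clade, site_truth


def simulate_specimen_metadata(
    n_before: int,
    n_after: int,
    clade_counts: tuple[int, int, int, int] = (1, 6, 10, 2),
    seed: int = 0,
) -> list[SpecimenRecord]:
    """Dated European find-context specimens for the chronology analysis.

    ``clade_counts`` is ``(west_before, east_before, west_after, east_after)``;
    date ranges fall strictly inside (800, 1125) for the early period and
    (1125, 1400) for the late period, so midpoint classification reproduces
    the intended period membership by construction.
    """
    wb, eb, wa, ea = clade_counts
    if wb + eb != n_before or wa + ea != n_after:
        raise ValueError("clade_counts inconsistent with period sizes")
    rng = np.random.default_rng(seed)
    records: list[SpecimenRecord] = []

    def draw(lo: int, hi: int) -> tuple[int, int]:
        a, b = sorted(rng.integers(lo + 1, hi, size=2))
        return int(a), int(b)

    k = 0
    for clade, n, (lo, hi) in (
        ("western", wb, (800, 1125)), ("eastern", eb, (800, 1125)),
        ("western", wa, (1125, 1400)), ("eastern", ea, (1125, 1400)),
    ):
        for _ in range(n):
            k += 1
            d0, d1 = draw(lo, hi)
            records.append(
                SpecimenRecord(
                    id=f"S{k:03d}",
                    location=f"site_{k:03d}",
                    region="Europe_find",
                    date_lo=d0,
                    date_hi=d1,
                    true_clade=clade,
                )
            )
    return records


def simulate_cr_population(cfg: CrPopConfig) -> pd.DataFrame:
    """Control-region genotypes at the three scored positions, per individual.

    Each individual in region r carries the ACC haplotype with probability
    ``acc_frequency[r]``, otherwise one of the fixed alternative haplotypes
    drawn uniformly.  Columns: id, region, pos15564, pos15760, pos15779.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    k = 0
    for region in sorted(cfg.region_sizes):
        n = cfg.region_sizes[region]
        f = cfg.acc_frequency[region]
        for _ in range(n):
            k += 1
            if rng.random() < f:
                hap = ACC
            else:
                hap = ALT_HAPLOTYPES[rng.integers(len(ALT_HAPLOTYPES))]
            rows.append({
                "id": f"CR{k:04d}", "region": region,
                "pos15564": hap[0], "pos15760": hap[1], "pos15779": hap[2],
            })
    return pd.DataFrame(rows, columns=["id", "region", "pos15564", "pos15760", "pos15779"])


METADATA_COLUMNS = ["id", "location", "region", "date_lo", "date_hi", "true_clade"]


def write_metadata(records: list[SpecimenRecord], path, include_truth: bool = True) -> None:
    cols = METADATA_COLUMNS if include_truth else METADATA_COLUMNS[:-1]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(columns=METADATA_COLUMNS)
    df[cols].to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "location": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenRecord(
                id=row["id"], location=row["location"], region=row["region"],
                date_lo=int(row["date_lo"]), date_hi=int(row["date_hi"]),
                true_clade=row.get("true_clade", "unknown"),
            )
        )
    return records


def write_cr_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cr_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
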