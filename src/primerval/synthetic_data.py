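"""Synthetic reference databases with exact ground truth for every metric.

The generator emulates the statistical structure the evaluation assumes: a
family -> genus -> species taxonomy whose names are synthesized
deterministically (Fam001, Gen001_01, Sp001_01_02), primer binding sites
carrying a controlled per-site mismatch count, and an inter-primer variable
region evolved down the taxonomy tree so that divergence controls
resolution. Each record is

    left flank + forward site + variable region + revcomp(reverse site) + right flank

where the binding sites are the primer with degeneracies resolved to
concrete bases and ``k`` positions mutated to bases *outside* the primer's
IUPAC set (so sampled mismatch counts are realised exactly, never
under-realised). Mismatch counts are drawn by largest-remainder quota, so
the configured distribution holds exactly on every instance, and are drawn
per *species* (all sequences of a species share their binding sites and
variable region), which makes amplifiability — and hence post-dedup
specificity — independent of the deduplication seed.

The ground-truth object records, per record, the planted mismatch counts,
the variable region (= the expected metabarcode) and amplifiability, and can
recompute expected coverage, per-rank resolution and specificity by pure
bookkeeping, independently of the scanning engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .iupac import IUPAC_SETS, reverse_complement
from .refdb_io import PrimerPair, ReferenceRecord, write_reference_db
from .taxonomy import Lineage

BASES = "ACGT"
#: phyla assigned to non-target clades, cycled per family
NONTARGET_PHYLA = ("Arthropoda", "Annelida", "Mollusca", "Rotifera")

DEFAULT_TARGET_MM = {0: 0.55, 1: 0.20, 2: 0.10, 3: 0.05, 4: 0.10}
DEFAULT_NONTARGET_MM = {0: 0.05, 1: 0.05, 2: 0.10, 3: 0.10, 4: 0.70}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for the generator.

    Default clade shape mirrors the proportions of a curated 18S nematode
    reference database (about 3 genera per family, 4 species per genus and 2
    sequences per species), scaled to 8 families. The mismatch-count maps
    give the probability that a binding site carries exactly 0-3 mismatches
    or >= 4 (key 4), separately for target and non-target clades.
    """

    seed: int = 0
    n_families: int = 8
    genera_per_family: int = 3
    species_per_genus: int = 4
    seqs_per_species: int = 2
    target_fraction: float = 0.5
    target_mismatch_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_MM))
    nontarget_mismatch_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_NONTARGET_MM))
    variable_region_length: tuple[int, int] = (150, 380)
    species_divergence: float = 0.02
    genus_divergence: float = 0.05
    shared_metabarcode_fraction: float = 0.0
    flank_length: tuple[int, int] = (20, 60)
    target_phylum: str = "Nematoda"

    def __post_init__(self):
        for name, dist in (("target", self.target_mismatch_distribution),
                           ("nontarget", self.nontarget_mismatch_distribution)):
            if set(dist) - {0, 1, 2, 3, 4}:
                raise ValueError(f"{name} distribution keys must be 0..4 "
                                 "(4 meaning '4 or more')")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} mismatch probabilities must sum to 1")
        if not (0.0 <= self.species_divergence < 1.0
                and 0.0 <= self.genus_divergence < 1.0):
            raise ValueError("divergences must lie in [0, 1)")
        lo, hi = self.variable_region_length
        if not (0 < lo <= hi):
            raise ValueError("variable_region_length must be positive min<=max")
        if not (0.0 <= self.shared_metabarcode_fraction <= 1.0):
            raise ValueError("shared_metabarcode_fraction must lie in [0, 1]")
        if min(self.n_families, self.genera_per_family,
               self.species_per_genus, self.seqs_per_species) < 1:
            raise ValueError("clade shape counts must be >= 1")


@dataclass
class GroundTruth:
    """Generator bookkeeping; the oracle for coverage, resolution and
    specificity on the generated instance."""

    target_phylum: str
    primer_name: str
    min_len: int
    max_len: int
    #: rid -> dict(species, genus, family, phylum, fwd_mm, rev_mm,
    #:            region_len, metabarcode, amplifiable)
    per_record: dict[str, dict]
    shared_pairs: list[tuple[str, str]] = field(default_factory=list)

    def _amplifiable(self, info: dict, max_mismatches: int = 3) -> bool:
        return (info["fwd_mm"] <= max_mismatches
                and info["rev_mm"] <= max_mismatches
                and self.min_len <= info["region_len"] <= self.max_len)

    def amplifiable_ids(self, max_mismatches: int = 3) -> list[str]:
        return sorted(rid for rid, info in self.per_record.items()
                      if self._amplifiable(info, max_mismatches))

    def expected_coverage(self, max_mismatches: int = 3) -> float:
        ids = self.amplifiable_ids(max_mismatches)
        return len(ids) / len(self.per_record)

    def expected_resolution(self, rank: str, max_mismatches: int = 3
                            ) -> float | None:
        groups: dict[str, set[str]] = {}
        for rid in self.amplifiable_ids(max_mismatches):
            info = self.per_record[rid]
            groups.setdefault(info["metabarcode"], set()).add(info[rank])
        if not groups:
            return None
        return sum(1 for taxa in groups.values() if len(taxa) == 1) / len(groups)

    def expected_specificity(self, max_mismatches: int = 3
                             ) -> tuple[float | None, int]:
        """Post-dedup specificity: amplifiability is per species by
        construction, so the dedup seed cannot change this value."""
        amplified_species: dict[str, str] = {}
        for rid in self.amplifiable_ids(max_mismatches):
            info = self.per_record[rid]
            amplified_species[info["species"]] = info["phylum"]
        if not amplified_species:
            return None, 0
        n_target = sum(1 for ph in amplified_species.values()
                       if ph == self.target_phylum)
        return n_target / len(amplified_species), n_target

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["shared_pairs"] = [list(p) for p in self.shared_pairs]
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            payload = json.load(handle)
        payload["shared_pairs"] = [tuple(p) for p in payload["shared_pairs"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# sampling helpers

def _quota_counts(dist: Mapping[int, float], n: int,
                  rng: np.random.Generator) -> list[int]:
    """n draws realising ``dist`` exactly (largest-remainder apportionment,
    then a seeded shuffle)."""
    keys = sorted(dist)
    ideal = {k: dist[k] * n for k in keys}
    counts = {k: int(ideal[k]) for k in keys}
    short = n - sum(counts.values())
    remainders = sorted(keys, key=lambda k: (-(ideal[k] - counts[k]), k))
    for k in remainders[:short]:
        counts[k] += 1
    draws = [k for k in keys for _ in range(counts[k])]
    rng.shuffle(draws)
    return draws


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution with probability ``rate`` (never to itself)."""
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    return "".join(chars)


def _planted_site(primer: str, n_mismatches: int,
                  rng: np.random.Generator) -> str:
    """A concrete binding site: degeneracies resolved at random, then
    ``n_mismatches`` positions flipped to bases *outside* the primer's IUPAC
    set there (so every planted mismatch is a true mismatch)."""
    site = [rng.choice(sorted(IUPAC_SETS[c])) for c in primer]
    mutable = [i for i, c in enumerate(primer) if len(IUPAC_SETS[c]) < 4]
    if n_mismatches > len(mutable):
        raise ValueError(
            f"cannot plant {n_mismatches} mismatches: primer has only "
            f"{len(mutable)} non-N positions"
        )
    for i in rng.choice(mutable, size=n_mismatches, replace=False):
        site[i] = rng.choice(sorted(set(BASES) - IUPAC_SETS[primer[i]]))
    return "".join(site)


# ---------------------------------------------------------------------------
# generators

def _check_feasible(config: SyntheticConfig, pair: PrimerPair,
                    dists: Sequence[Mapping[int, float]]) -> None:
    lo, hi = config.variable_region_length
    expects_amplification = any(
        sum(p for k, p in dist.items() if k <= 3) > 0 for dist in dists
    )
    if expects_amplification and (hi < pair.min_len or lo > pair.max_len):
        raise ValueError(
            f"infeasible config: variable_region_length {lo}-{hi} bp never "
            f"falls inside primer bounds {pair.min_len}-{pair.max_len} bp "
            "although the mismatch distribution expects amplification"
        )


def _generate_clade(config: SyntheticConfig, pair: PrimerPair,
                    rng: np.random.Generator, phyla: Sequence[str],
                    n_families: int, family_offset: int,
                    mm_dist: Mapping[int, float]
                    ) -> tuple[list[ReferenceRecord], dict[str, dict],
                               list[tuple[str, str]]]:
    records: list[ReferenceRecord] = []
    per_record: dict[str, dict] = {}
    n_species = n_families * config.genera_per_family * config.species_per_genus
    # Comonotone pairing: the rank-aligned forward and reverse draws give a
    # species with a poor forward site an equally poor reverse site, so the
    # amplifiable fraction of a clade is exactly the probability mass the
    # distribution puts on counts <= 3, and clades with identical
    # distributions amplify identically.
    mm_pairs = list(zip(sorted(_quota_counts(mm_dist, n_species, rng)),
                        sorted(_quota_counts(mm_dist, n_species, rng))))
    rng.shuffle(mm_pairs)
    fwd_counts = [f for f, _ in mm_pairs]
    rev_counts = [r for _, r in mm_pairs]

    # species regions, evolved family -> genus -> species
    species_meta: list[tuple[str, str, str, str]] = []  # (sp, gen, fam, phy)
    regions: dict[str, str] = {}
    lo, hi = config.variable_region_length
    for fi in range(n_families):
        fam_id = family_offset + fi + 1
        family = f"Fam{fam_id:03d}"
        phylum = phyla[fi % len(phyla)]
        fam_region = _random_seq(int(rng.integers(lo, hi + 1)), rng)
        for gi in range(config.genera_per_family):
            genus = f"Gen{fam_id:03d}_{gi + 1:02d}"
            gen_region = _mutate(fam_region, config.genus_divergence, rng)
            for si in range(config.species_per_genus):
                species = f"Sp{fam_id:03d}_{gi + 1:02d}_{si + 1:02d}"
                regions[species] = _mutate(gen_region,
                                           config.species_divergence, rng)
                species_meta.append((species, genus, family, phylum))

    # force metabarcode sharing on a fraction of within-genus species pairs
    shared: list[tuple[str, str]] = []
    if config.shared_metabarcode_fraction > 0:
        pairs = []
        for i in range(0, len(species_meta) - 1, 2):
            a, b = species_meta[i], species_meta[i + 1]
            if a[1] == b[1]:  # same genus
                pairs.append((a[0], b[0]))
        n_shared = round(config.shared_metabarcode_fraction * len(pairs))
        for idx in rng.choice(len(pairs), size=n_shared, replace=False):
            a, b = pairs[int(idx)]
            regions[b] = regions[a]
            shared.append((a, b))

    for (species, genus, family, phylum), fwd_mm, rev_mm in zip(
            species_meta, fwd_counts, rev_counts):
        fwd_plant = 4 if fwd_mm == 4 else fwd_mm
        rev_plant = 4 if rev_mm == 4 else rev_mm
        fwd_site = _planted_site(pair.forward, fwd_plant, rng)
        rev_site = _planted_site(pair.reverse, rev_plant, rng)
        region = regions[species]
        core = fwd_site + region + reverse_complement(rev_site)
        lineage = Lineage({
            "phylum": phylum,
            "class": f"Class{family[3:]}",
            "order": f"Order{family[3:]}",
            "family": family,
            "genus": genus,
            "species": species,
        })
        flo, fhi = config.flank_length
        for k in range(config.seqs_per_species):
            rid = f"{species}_r{k + 1:02d}"
            left = _random_seq(int(rng.integers(flo, fhi + 1)), rng)
            right = _random_seq(int(rng.integers(flo, fhi + 1)), rng)
            records.append(ReferenceRecord(rid, left + core + right, lineage))
            per_record[rid] = {
                "species": species, "genus": genus, "family": family,
                "phylum": phylum, "fwd_mm": fwd_mm, "rev_mm": rev_mm,
                "region_len": len(region), "metabarcode": region,
                "amplifiable": (fwd_mm <= 3 and rev_mm <= 3
                                and pair.min_len <= len(region) <= pair.max_len),
            }
    return records, per_record, shared


def generate_db(config: SyntheticConfig, pair: PrimerPair
                ) -> tuple[list[ReferenceRecord], GroundTruth]:
    """Single-phylum reference database (all records in the target phylum)
    with exact per-record amplifiability and metabarcode bookkeeping."""
    _check_feasible(config, pair, [config.target_mismatch_distribution])
    rng = np.random.default_rng(config.seed)
    records, per_record, shared = _generate_clade(
        config, pair, rng, [config.target_phylum], config.n_families, 0,
        config.target_mismatch_distribution)
    truth = GroundTruth(config.target_phylum, pair.name, pair.min_len,
                        pair.max_len, per_record, shared)
    return records, truth


def generate_mixed_phylum_db(config: SyntheticConfig, pair: PrimerPair
                             ) -> tuple[list[ReferenceRecord], GroundTruth]:
    """Mixed target/non-target database for the specificity analysis.

    ``target_fraction`` sets the share of families (hence records) in the
    target phylum; the two clades get their own binding-site mismatch
    distributions. Species multiplicities > 1 (``seqs_per_species``)
    exercise the one-sequence-per-species deduplication.
    """
    if not (0.0 < config.target_fraction < 1.0):
        raise ValueError("target_fraction must lie strictly in (0, 1)")
    _check_feasible(config, pair, [config.target_mismatch_distribution,
                                   config.nontarget_mismatch_distribution])
    n_target_fam = min(max(round(config.target_fraction * config.n_families), 1),
                       config.n_families - 1)
    rng = np.random.default_rng(config.seed)
    t_records, t_truth, t_shared = _generate_clade(
        config, pair, rng, [config.target_phylum], n_target_fam, 0,
        config.target_mismatch_distribution)
    nt_records, nt_truth, nt_shared = _generate_clade(
        config, pair, rng, NONTARGET_PHYLA,
        config.n_families - n_target_fam, n_target_fam,
        config.nontarget_mismatch_distribution)
    truth = GroundTruth(config.target_phylum, pair.name, pair.min_len,
                        pair.max_len, {**t_truth, **nt_truth},
                        t_shared + nt_shared)
    return t_records + nt_records, truth


def write_db(records: Sequence[ReferenceRecord], truth: GroundTruth,
             out_dir: str | Path) -> Path:
    """Emit db.fasta + lineage.tsv (the dialects refdb_io reads) and
    ground_truth.json. Byte-identical for identical seed and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_reference_db(records, out / "db.fasta", out / "lineage.tsv")
    truth.to_json(out / "ground_truth.json")
    return out
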