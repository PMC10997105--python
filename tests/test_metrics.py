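import random

import pytest

from primerval import (
    MetabarcodeGroup,
    ReferenceRecord,
    amplify_db,
    build_report,
    coverage,
    dedup_one_per_species,
    generate_db,
    group_metabarcodes,
    resolution,
    specificity,
)
from primerval.metrics import EXCLUDE, UNRESOLVED
from primerval.synthetic_data import SyntheticConfig

from conftest import make_lineage


def group(metabarcode, *lineages):
    return MetabarcodeGroup(
        metabarcode,
        tuple((f"m{i}", lin) for i, lin in enumerate(lineages)))


def lin(genus, species=None, family="Rhabditidae"):
    return make_lineage(family=family, genus=genus, species=species)


class TestCoverage:
    def test_three_of_four(self, euka02):
        result = amplify_db([], euka02, 3)
        result.n_total = 4
        result.designated = {f"r{i}": None for i in range(3)}
        assert coverage(result) == 0.75

    def test_empty_db_raises(self, euka02):
        with pytest.raises(ValueError):
            coverage(amplify_db([], euka02, 3))


class TestGroupMetabarcodes:
    @pytest.fixture
    def synthetic(self, euka02):
        cfg = SyntheticConfig(seed=21, shared_metabarcode_fraction=0.25)
        records, truth = generate_db(cfg, euka02)
        return records, truth, amplify_db(records, euka02, 3)

    def test_groups_partition_amplified_records(self, synthetic):
        records, _, result = synthetic
        groups = group_metabarcodes(result, records)
        assert sum(g.size for g in groups) == result.n_amplified
        ids = [rid for g in groups for rid, _ in g.members]
        assert sorted(ids) == result.amplified_ids

    def test_forced_sister_species_share_a_group(self, synthetic):
        records, truth, result = synthetic
        groups = group_metabarcodes(result, records)
        by_rid_species = {rid: info["species"]
                          for rid, info in truth.per_record.items()}
        amplifiable = set(truth.amplifiable_ids())
        for sp_a, sp_b in truth.shared_pairs:
            rids = [rid for rid, sp in by_rid_species.items()
                    if sp in (sp_a, sp_b) and rid in amplifiable]
            if not rids:
                continue
            owning = [g for g in groups
                      if any(rid in {m for m, _ in g.members} for rid in rids)]
            # all records of the forced pair fall in exactly one group
            assert len({id(g) for g in owning}) == 1
            species_in_group = {by_rid_species[m]
                                for m, _ in owning[0].members}
            assert species_in_group <= {sp_a, sp_b}


class TestResolution:
    def test_congeneric_pair_resolves_genus_not_species(self):
        g = group("AAA", lin("Caenorhabditis", "C. elegans"),
                  lin("Caenorhabditis", "C. briggsae"))
        assert resolution([g], "species") == 0.0
        assert resolution([g], "genus") == 1.0
        assert resolution([g], "family") == 1.0

    def test_all_singletons_fully_resolved(self):
        groups = [group(f"BC{i}", lin(f"G{i}", f"G{i} sp")) for i in range(5)]
        for rank in ("species", "genus", "family"):
            assert resolution(groups, rank) == 1.0

    def test_incomplete_group_policies(self):
        complete = group("AAA", lin("G1", "G1 sp"))
        incomplete = group("CCC", lin("G2", None))  # no species annotation
        assert resolution([complete, incomplete], "species",
                          EXCLUDE) == 1.0
        assert resolution([complete, incomplete], "species",
                          UNRESOLVED) == 0.5

    def test_all_incomplete_is_undefined_with_warning(self):
        g = group("AAA", make_lineage(genus=None, species=None))
        with pytest.warns(UserWarning, match="undefined"):
            assert resolution([g], "species") is None

    def test_empty_groups_raise(self):
        with pytest.raises(ValueError):
            resolution([], "species")


class TestDedup:
    def test_many_records_one_species_keeps_one(self):
        records = [ReferenceRecord(f"r{i}", "ACGT",
                                   lin("Caenorhabditis", "C. elegans"))
                   for i in range(10)]
        assert len(dedup_one_per_species(records, 1)) == 1

    def test_same_seed_reproducible(self):
        rng = random.Random(12)
        records = [
            ReferenceRecord(f"r{i}", "ACGT",
                            lin(f"G{i % 7}", f"G{i % 7} sp{i % 13}"))
            for i in range(60)
        ]
        first = [r.record_id for r in dedup_one_per_species(records, 99)]
        second = [r.record_id for r in dedup_one_per_species(records, 99)]
        assert first == second

    def test_one_record_per_known_species_count(self):
        rng = random.Random(13)
        species = [f"Sp{i:02d}" for i in range(40)]
        records = []
        for i in range(100):
            sp = rng.choice(species)
            records.append(ReferenceRecord(f"r{i}", "ACGT", lin("G", sp)))
        present = {f"Sp{i:02d}" for i in range(40)} & \
            {r.lineage.ranks["species"] for r in records}
        assert len(dedup_one_per_species(records, 7)) == len(present)

    def test_species_unannotated_records_kept_as_singletons(self):
        records = [ReferenceRecord(f"r{i}", "ACGT", make_lineage())
                   for i in range(5)]
        assert len(dedup_one_per_species(records, 1)) == 5


class TestSpecificity:
    def test_five_target_of_fifty(self):
        target = [ReferenceRecord(f"t{i}", "ACGT",
                                  lin("G", f"Nem sp{i}"))
                  for i in range(5)]
        other = [ReferenceRecord(
            f"o{i}", "ACGT",
            make_lineage(phylum="Arthropoda", family="F",
                         genus="G", species=f"Art sp{i}"))
            for i in range(45)]
        frac, n_sp = specificity(target + other, "Nematoda")
        assert frac == pytest.approx(0.10)
        assert n_sp == 5

    def test_all_target_is_one(self):
        records = [ReferenceRecord(f"t{i}", "ACGT", lin("G", f"sp{i}"))
                   for i in range(8)]
        assert specificity(records, "Nematoda")[0] == 1.0

    def test_empty_amplified_set_warns_undefined(self):
        with pytest.warns(UserWarning):
            assert specificity([], "Nematoda") == (None, 0)


class TestBuildReport:
    def test_report_satisfies_invariants_on_synthetic_db(self, euka02):
        cfg = SyntheticConfig(seed=31, n_families=5,
                              shared_metabarcode_fraction=0.2)
        records, _ = generate_db(cfg, euka02)
        result = amplify_db(records, euka02, 3)
        rep = build_report(result, records)
        assert rep.resolution_species <= rep.resolution_genus \
            <= rep.resolution_family
        assert rep.n_amplified <= rep.n_total
        assert rep.coverage == rep.n_amplified / rep.n_total
        assert rep.min_len_obs <= rep.mean_len <= rep.max_len_obs
        assert euka02.min_len <= rep.min_len_obs
        assert rep.max_len_obs <= euka02.max_len

    def test_zero_amplification_report(self, euka02):
        records = [ReferenceRecord("r1", "ACGT" * 100, make_lineage())]
        rep = build_report(amplify_db(records, euka02, 0), records)
        assert rep.coverage == 0.0
        assert rep.resolution_species is None and rep.mean_len is None
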