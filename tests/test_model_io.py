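import json

from hypothesis import given, settings
from hypothesis import strategies as st

import numpy as np
import pandas as pd
import pytest

from commflux.model_io import (
    AbundanceTable,
    DietSpec,
    FormatError,
    Metabolite,
    Reaction,
    StrainReconstruction,
    Taxonomy,
    ValidationError,
    parse_formula,
    read_abundance_table,
    read_diet_file,
    read_strain_reconstruction,
    write_abundance_table,
    write_diet_file,
    write_strain_reconstruction,
)


def _tax(strain="S1"):
    return Taxonomy("P", "C", "O", "F", "G", "G sp", strain)


def minimal_strain():
    """Three-reaction model: substrate uptake, biomass, product secretion."""
    mets = {
        "glc": Metabolite("glc", "glucose", "C6H12O6"),
        "lac": Metabolite("lac", "lactate", "C3H5O3"),
        "bm": Metabolite("bm", "biomass", ""),
    }
    rxns = {
        "EX_glc": Reaction("EX_glc", {"glc": -1}, -10, 0, "Exchange"),
        "EX_lac": Reaction("EX_lac", {"lac": -1}, 0, 1000, "Exchange"),
        "EX_bm": Reaction("EX_bm", {"bm": -1}, 0, 1000, "Exchange"),
        "GROW": Reaction("GROW", {"glc": -1, "lac": 1, "bm": 1}, 0, 1000, "Core"),
    }
    return StrainReconstruction("S1", _tax(), mets, rxns, "GROW")


class TestFormulaParsing:
    # brute-force oracle: scan characters, accumulate symbol+digits
    @staticmethod
    def _oracle_has_sulfur(formula):
        i, n = 0, len(formula)
        while i < n:
            sym = formula[i]
            i += 1
            if i < n and formula[i].islower():
                sym += formula[i]
                i += 1
            while i < n and formula[i].isdigit():
                i += 1
            if sym == "S":
                return True
        return False

    FORMULAS = [
        "C6H12O6", "H2S", "O4S", "O3S2", "CH4S", "C2H6S", "SO4", "S",
        "Se", "Sn", "SeS", "NaSO4", "C10H17N3O6S", "CSeH2", "S2", "SnS",
        "C5H11NO2Se", "Fe2O3", "", "C12H17N4OS",
    ]

    @pytest.mark.parametrize("formula", FORMULAS)
    def test_is_sulfur_matches_elementwise_parse(self, formula):
        met = Metabolite("x", "x", formula)
        assert met.is_sulfur == self._oracle_has_sulfur(formula)

    def test_two_letter_symbols_take_precedence(self):
        assert parse_formula("Se") == {"Se": 1}
        assert parse_formula("Sn2") == {"Sn": 2}
        assert parse_formula("S2") == {"S": 2}

    @pytest.mark.parametrize("bad", ["c6h12", "C6(H12)", "6C", "C-6"])
    def test_malformed_formula_raises(self, bad):
        with pytest.raises(FormatError):
            parse_formula(bad)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["C", "H", "O", "N", "P", "S", "Se", "Sn", "Fe"]),
                st.integers(min_value=1, max_value=99),
            ),
            max_size=8,
        )
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_parse_counts_assembled_formulas(self, parts):
        formula = "".join(f"{sym}{n}" for sym, n in parts)
        counts = parse_formula(formula)
        expected = {}
        for sym, n in parts:
            expected[sym] = expected.get(sym, 0) + n
        assert counts == expected
        assert Metabolite("x", "", formula).is_sulfur == (
            expected.get("S", 0) > 0
        )


class TestStrainRoundTrip:
    def test_minimal_model_structure(self, tmp_path):
        path = tmp_path / "s.json"
        write_strain_reconstruction(minimal_strain(), path, "json")
        model = read_strain_reconstruction(path, "json")
        assert model.biomass_reaction_id == "GROW"
        assert sorted(model.exchange_reaction_ids) == ["EX_bm", "EX_glc", "EX_lac"]

    @pytest.mark.parametrize("format", ["json", "sbml"])
    def test_round_trip_identity(self, strain_set, tmp_path, format):
        suffix = "json" if format == "json" else "xml"
        subset = strain_set if format == "json" else strain_set[:6]
        for strain in subset:
            path = tmp_path / f"{strain.strain_id}.{suffix}"
            write_strain_reconstruction(strain, path, format)
            back = read_strain_reconstruction(path, format)
            assert back.strain_id == strain.strain_id
            assert back.taxonomy == strain.taxonomy
            assert back.metabolites == strain.metabolites
            assert set(back.reactions) == set(strain.reactions)
            for rid, rxn in strain.reactions.items():
                other = back.reactions[rid]
                assert other.stoichiometry == rxn.stoichiometry
                # bounds preserved exactly, no float drift
                assert other.lower_bound == rxn.lower_bound
                assert other.upper_bound == rxn.upper_bound
                assert other.subsystem == rxn.subsystem
            assert back.biomass_reaction_id == strain.biomass_reaction_id

    def test_cross_format_round_trip(self, strain_set, tmp_path):
        for strain in strain_set[:3]:
            j1 = tmp_path / "a.json"
            x1 = tmp_path / "a.xml"
            write_strain_reconstruction(strain, j1, "json")
            m1 = read_strain_reconstruction(j1, "json")
            write_strain_reconstruction(m1, x1, "sbml")
            m2 = read_strain_reconstruction(x1, "sbml")
            assert m1.metabolites == m2.metabolites
            assert {r: m1.reactions[r].stoichiometry for r in m1.reactions} == {
                r: m2.reactions[r].stoichiometry for r in m2.reactions
            }

    def test_biomass_without_flux_fails_validation(self, tmp_path):
        # biomass consumes a metabolite nothing imports or produces
        model = minimal_strain()
        model.reactions["GROW"].stoichiometry["orphan"] = -1.0
        model.metabolites["orphan"] = Metabolite("orphan", "", "")
        path = tmp_path / "bad.json"
        write_strain_reconstruction(model, path, "json")
        with pytest.raises(ValidationError, match="cannot carry flux"):
            read_strain_reconstruction(path, "json")

    def test_dangling_metabolite_reference_names_reaction(self):
        model = minimal_strain()
        model.reactions["GROW"].stoichiometry["ghost"] = 1.0
        with pytest.raises(ValidationError, match="GROW"):
            model.validate()

    def test_missing_biomass_is_validation_error(self):
        model = minimal_strain()
        model.biomass_reaction_id = "NOPE"
        with pytest.raises(ValidationError, match="biomass"):
            model.validate()

    def test_parse_failure_reports_format_error(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{not json")
        with pytest.raises(FormatError):
            read_strain_reconstruction(path, "json")


class TestAbundanceTable:
    def _write(self, tmp_path, rows, strains=("s1", "s2", "s3")):
        lines = ["sample_id\tgroup\t" + "\t".join(strains)]
        for sid, group, vals in rows:
            lines.append(f"{sid}\t{group}\t" + "\t".join(str(v) for v in vals))
        path = tmp_path / "ab.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_cutoff_drops_and_renormalises(self, tmp_path):
        path = self._write(tmp_path, [("A", "healthy", [0.5, 0.5, 0.0])])
        table = read_abundance_table(path, cutoff=1e-6)
        assert table.sample("A") == {"s1": 0.5, "s2": 0.5}

    def test_renormalisation_example(self, tmp_path):
        path = self._write(
            tmp_path, [("A", "healthy", [0.6, 0.3999999, 1e-7])]
        )
        table = read_abundance_table(path, cutoff=1e-6)
        sample = table.sample("A")
        assert sample["s1"] == pytest.approx(0.6, abs=1e-6)
        assert sample["s2"] == pytest.approx(0.4, abs=1e-6)
        assert "s3" not in sample

    def test_rows_sum_to_one(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = [
            (f"S{i}", "healthy", rng.dirichlet([1, 1, 1]) * rng.uniform(0.5, 2))
            for i in range(20)
        ]
        table = read_abundance_table(self._write(tmp_path, rows), cutoff=1e-6)
        assert np.allclose(table.values.sum(axis=1), 1.0, atol=1e-8)

    def test_zero_row_raises(self, tmp_path):
        path = self._write(tmp_path, [("A", "healthy", [0, 0, 0])])
        with pytest.raises(ValidationError, match="zero"):
            read_abundance_table(path)

    def test_negative_abundance_raises(self, tmp_path):
        path = self._write(tmp_path, [("A", "healthy", [-0.1, 0.6, 0.5])])
        with pytest.raises(ValidationError, match="negative"):
            read_abundance_table(path)

    def test_unknown_group_raises(self, tmp_path):
        path = self._write(tmp_path, [("A", "sick", [0.5, 0.5, 0.0])])
        with pytest.raises(ValidationError, match="group"):
            read_abundance_table(path)

    def test_write_read_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.tsv"
        write_abundance_table(small_cohort, path)
        back = read_abundance_table(path, cutoff=0)
        assert np.allclose(back.values.values, small_cohort.values.values, atol=1e-12)
        assert (back.group == small_cohort.group).all()


class TestDietFile:
    def test_duplicate_rows_summed(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("glc_D\t10\nglc_D\t5\n")
        diet = read_diet_file(path)
        assert diet.uptake_limits == {"glc_D": 15.0}

    def test_empty_file_is_valid(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("# nothing\n")
        assert read_diet_file(path).uptake_limits == {}

    def test_negative_amount_raises(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("glc_D\t-1\n")
        with pytest.raises(ValidationError):
            read_diet_file(path)

    def test_unparseable_amount_raises(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("glc_D\tten\n")
        with pytest.raises(FormatError, match="ten"):
            read_diet_file(path)

    def test_round_trip(self, tmp_path, diet):
        path = tmp_path / "d.tsv"
        write_diet_file(diet, path)
        back = read_diet_file(path, host_metabolites=diet.host_metabolites)
        assert back.uptake_limits == diet.uptake_limits
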