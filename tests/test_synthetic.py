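import pytest

from cliffscape import (
    CliffInjection,
    DADLabel,
    LandscapeThresholds,
    RegionLabel,
    SeriesSpec,
    build_sas_map,
    cliff_generator_frequencies,
    default_series_spec,
    expected_landscape,
    generate_series,
    recovery_series_spec,
)


def tiny_spec(**overrides) -> SeriesSpec:
    kwargs = dict(
        scaffold="[*:1]c1ccc([*:2])cc1",
        r_groups={1: ["[*]C", "[*]O", "[*]N", "[*]F", "[*]Cl"],
                  2: ["[*]C", "[*]CC", "[*]OC", "[*]CO", "[*]CN"]},
        base_activity={"X": 6.0, "Y": 5.5},
        contributions={
            "X": {1: [0.0, 0.2, 0.4, -0.2, 0.1], 2: [0.0, 0.1, 0.3, -0.1, 0.2]},
            "Y": {1: [0.0, 0.1, 0.2, -0.1, 0.0], 2: [0.0, 0.0, 0.1, -0.1, 0.1]},
        },
        noise_sd=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return SeriesSpec(**kwargs)


class TestGenerateSeries:
    def test_zero_noise_additivity(self):
        table, truth = generate_series(tiny_spec())
        assert len(table) == 25
        for cid, combo in truth.assignments.items():
            rec = table.compounds[table.index_of(cid)]
            for target in ("X", "Y"):
                expected = 6.0 if target == "X" else 5.5
                spec = tiny_spec()
                for pos, sub in combo.items():
                    expected += spec.contributions[target][pos][sub]
                assert rec.activities[target] == pytest.approx(expected)

    def test_injected_gap_exact(self):
        inj = CliffInjection(a=((1, 0), (2, 0)), b=((1, 0), (2, 1)),
                             target="X", delta=3.0)
        table, truth = generate_series(
            tiny_spec(noise_sd=0.15, cliff_injections=[inj])
        )
        (pair,) = truth.injected_pairs
        a = table.compounds[table.index_of(pair["i"])].activities["X"]
        b = table.compounds[table.index_of(pair["j"])].activities["X"]
        assert a - b == pytest.approx(3.0)

    def test_deterministic_under_seed(self):
        t1, _ = generate_series(tiny_spec(noise_sd=0.2, seed=42))
        t2, _ = generate_series(tiny_spec(noise_sd=0.2, seed=42))
        assert t1.to_dataframe().equals(t2.to_dataframe())
        t3, _ = generate_series(tiny_spec(noise_sd=0.2, seed=43))
        assert not t1.to_dataframe().equals(t3.to_dataframe())

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="cap"):
            tiny_spec(enumeration_cap=10)

    def test_invalid_fragment_named(self):
        with pytest.raises(ValueError, match="C1CC"):
            spec = tiny_spec()
            spec.r_groups[1][0] = "[*]C1CC"
            generate_series(spec)

    def test_products_are_valid_molecules(self):
        from rdkit import Chem

        table, _ = generate_series(tiny_spec())
        for rec in table.compounds:
            assert Chem.MolFromSmiles(rec.smiles) is not None

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        spec = tiny_spec(noise_sd=0.1)
        raw = {
            "scaffold": spec.scaffold,
            "r_groups": {str(k): v for k, v in spec.r_groups.items()},
            "base_activity": spec.base_activity,
            "contributions": {
                t: {str(p): v for p, v in per.items()}
                for t, per in spec.contributions.items()
            },
            "noise_sd": spec.noise_sd,
            "seed": 7,
            "cliff_injections": [
                {"a": {"1": 0, "2": 0}, "b": {"1": 0, "2": 1},
                 "target": "X", "delta": 2.5}
            ],
        }
        path = tmp_path / "spec.yaml"
        path.write_text(yaml.safe_dump(raw))
        loaded = SeriesSpec.from_yaml(path)
        table, truth = generate_series(loaded)
        assert len(table) == 25
        assert len(truth.injected_pairs) == 1


class TestExpectedLandscape:
    def test_injected_cliff_expected(self):
        spec = recovery_series_spec(seed=0)
        expected = expected_landscape(spec)
        cliffs = expected["activity_cliff_pairs"]["G9a"]
        assert len(cliffs) == 6  # five generator cliffs + the switch
        assert all("12" in pair or pair == ("7", "8") for pair in cliffs)

    def test_matched_analogs_expected_smooth(self):
        spec = recovery_series_spec(seed=0, noise_sd=0.05)
        expected = expected_landscape(spec)
        assert len(expected["smooth_sar_pairs"]) > 0
        injected = {frozenset(p) for p in expected["activity_cliff_pairs"]["G9a"]}
        for pair in expected["smooth_sar_pairs"]:
            assert frozenset(pair) not in injected

    def test_switch_expected_selective_x(self):
        expected = expected_landscape(recovery_series_spec(seed=0))
        assert expected["dad_labels"]["7-8"] == DADLabel.SELECTIVE_X.value

    def test_noise_warning(self, caplog):
        spec = recovery_series_spec(seed=0, noise_sd=0.5)
        with caplog.at_level("WARNING"):
            expected_landscape(spec)
        assert any("unreliable" in r.message for r in caplog.records)


class TestPipelineOnSyntheticGroundTruth:
    def test_injected_pairs_become_cliffs_and_top_sali(self):
        table, truth = generate_series(recovery_series_spec(seed=3))
        sas = build_sas_map(table, schemes=["MACCS"])
        salis = sorted(
            (p.sali[("MACCS", "G9a")] for p in sas.pairs), reverse=True
        )
        top_decile = salis[len(salis) // 10 - 1]
        for inj in truth.injected_pairs:
            pair = next(
                p for p in sas.pairs if {p.i, p.j} == {inj["i"], inj["j"]}
            )
            assert pair.region[("MACCS", "G9a")] is RegionLabel.ACTIVITY_CLIFF
            assert pair.sali[("MACCS", "G9a")] >= top_decile

    def test_flat_series_without_injections_has_no_cliffs(self):
        spec = recovery_series_spec(seed=0, noise_sd=0.0)
        spec.cliff_injections = []
        table, _ = generate_series(spec)
        sas = build_sas_map(table, schemes=["MACCS"])
        for target in ("G9a", "DNMT1"):
            assert all(
                p.region[("MACCS", target)] is not RegionLabel.ACTIVITY_CLIFF
                for p in sas.pairs
            )

    def test_designated_generator_ranks_first(self):
        table, truth = generate_series(recovery_series_spec(seed=5))
        sas = build_sas_map(table, schemes=["MACCS"])
        freqs = cliff_generator_frequencies(sas, "MACCS", "G9a")
        assert next(iter(freqs)) == truth.generator_id == "12"

    def test_default_series_shape(self):
        table, truth = generate_series(default_series_spec(seed=1))
        assert len(table) == 50
        assert table.n_pairs == 1225
        assert truth.generator_id == "12"
        assert set(truth.expected_dad_labels.values()) <= {
            "SELECTIVE_X", "DUAL"
        }
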