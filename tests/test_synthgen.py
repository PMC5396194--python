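"""Generator contracts: determinism, stated-world recovery, planted truth."""

import numpy as np
import pandas as pd
import pytest

from kdrkit import doseresp, ephys, kdrseq, synthgen


class TestMortality:
    def test_determinism(self, table1_design):
        spec = synthgen.MortalitySimSpec(seed=42, **table1_design)
        a = synthgen.simulate_mortality(spec)
        b = synthgen.simulate_mortality(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, table1_design):
        a = synthgen.simulate_mortality(synthgen.MortalitySimSpec(seed=1, **table1_design))
        b = synthgen.simulate_mortality(synthgen.MortalitySimSpec(seed=2, **table1_design))
        assert not a["n_dead"].equals(b["n_dead"])

    def test_median_of_probit_curve(self):
        # at c = LC50 with no control mortality the observed kill converges to 50%
        spec = synthgen.MortalitySimSpec(
            true_lc50=1.0, true_slope=2.0, concentrations=(0.5, 1.0, 2.0),
            n_per_conc=100_000, seed=5,
        )
        table = synthgen.simulate_mortality(spec)
        at_lc50 = table[table.concentration == 1.0]
        p = float(at_lc50.n_dead.iloc[0] / at_lc50.n_exposed.iloc[0])
        assert p == pytest.approx(0.5, abs=0.01)

    def test_control_mortality_mixing_large_n(self):
        # empirical mortality at the LC50 converges to pi0 + (1 - pi0)/2
        pi0 = 0.1
        spec = synthgen.MortalitySimSpec(
            true_lc50=1.0, true_slope=2.0, concentrations=(0.5, 1.0, 2.0),
            n_per_conc=100_000, control_mortality=pi0, seed=6,
        )
        table = synthgen.simulate_mortality(spec)
        at_lc50 = table[table.concentration == 1.0]
        p = float(at_lc50.n_dead.iloc[0] / at_lc50.n_exposed.iloc[0])
        assert p == pytest.approx(pi0 + (1 - pi0) * 0.5, abs=0.01)

    def test_nonpositive_concentration_named_in_error(self):
        with pytest.raises(ValueError, match="-2"):
            synthgen.MortalitySimSpec(
                true_lc50=1.0, true_slope=2.0, concentrations=(-2.0, 1.0, 2.0)
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(concentrations=(2.0, 1.0, 3.0)),  # not increasing
            dict(concentrations=(1.0, 2.0), true_slope=-1.0),
            dict(concentrations=(1.0, 2.0), n_per_conc=0),
            dict(concentrations=(1.0, 2.0), control_mortality=1.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(true_lc50=1.0, true_slope=2.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            synthgen.MortalitySimSpec(**base)

    def test_refit_recovers_table1_parameters(self, table1_design):
        # design of the susceptible adult deltamethrin assay: mean refit LC50
        # within 5% of truth over replicates
        lc = []
        for i in range(60):
            spec = synthgen.MortalitySimSpec(seed=300 + i, **table1_design)
            table = synthgen.simulate_mortality(spec)
            fit = doseresp.fit_probit(table[table.concentration > 0])
            lc.append(fit.lc50_)
        assert np.mean(lc) == pytest.approx(7.6e-6, rel=0.05)


class TestTraces:
    def test_no_modified_channels_no_tail(self, protocol, channel_spec):
        trace, expected = synthgen.simulate_trace(protocol, channel_spec, 0.0)
        assert expected == 0.0
        # residual unmodified deactivation after blanking is below 0.1% of peak
        assert ephys.tail_amplitude(trace) < 1e-3 * ephys.peak_current(trace)

    def test_expected_m_matches_extraction_noiseless(self, protocol, channel_spec):
        for f in (0.1, 0.5, 0.9):
            trace, expected = synthgen.simulate_trace(protocol, channel_spec, f)
            measured = ephys.modification_result(trace, channel_spec.e_na).m_percent
            assert measured == pytest.approx(expected, rel=0.01)

    def test_expected_m_strictly_increasing_in_fraction(self, protocol, channel_spec):
        fracs = np.linspace(0.0, 1.0, 11)
        ems = [synthgen.simulate_trace(protocol, channel_spec, f)[1] for f in fracs]
        assert np.all(np.diff(ems) > 0)

    def test_trace_determinism(self, protocol):
        spec = synthgen.ChannelSimSpec(noise_sd=0.05, seed=9)
        a, _ = synthgen.simulate_trace(protocol, spec, 0.4)
        b, _ = synthgen.simulate_trace(protocol, spec, 0.4)
        np.testing.assert_array_equal(a.current, b.current)
        np.testing.assert_array_equal(a.pre_current, b.pre_current)

    def test_incommensurate_sample_interval_rejected(self, protocol):
        spec = synthgen.ChannelSimSpec(sample_interval=0.03)
        with pytest.raises(ValueError, match="incommensurate"):
            synthgen.simulate_trace(protocol, spec, 0.5)

    def test_modified_fraction_bounds(self, protocol, channel_spec):
        with pytest.raises(ValueError):
            synthgen.simulate_trace(protocol, channel_spec, 1.2)

    def test_tau_slow_must_dominate_deactivation(self):
        with pytest.raises(ValueError, match="tau_slow"):
            synthgen.ChannelSimSpec(tau_slow=0.5)


class TestVCExperiment:
    def test_hill_midpoint_and_plateau(self, channel_spec):
        em_mid = synthgen.expected_m(
            channel_spec, ephys.VoltageProtocol(),
            channel_spec.modified_fraction(channel_spec.ec50_true),
        )
        assert em_mid == pytest.approx(channel_spec.m_max / 2, rel=1e-6)
        em_sat = synthgen.expected_m(
            channel_spec, ephys.VoltageProtocol(),
            channel_spec.modified_fraction(channel_spec.ec50_true * 1e9),
        )
        assert em_sat == pytest.approx(channel_spec.m_max, rel=1e-6)

    def test_empty_concentration_list_rejected(self, channel_spec):
        with pytest.raises(ValueError, match="empty"):
            synthgen.simulate_vc_experiment(channel_spec, [], 3)

    def test_pipeline_recovers_ec50(self):
        # 5 oocytes x 6 concentrations at 2%-of-plateau noise: EC50 within 20%
        spec = synthgen.ChannelSimSpec(ec50_true=1e-7, seed=17)
        spec = synthgen.ChannelSimSpec(
            ec50_true=1e-7, seed=17,
            noise_sd=0.02 * synthgen.tail_noise_scale(spec),
        )
        records = synthgen.simulate_vc_experiment(spec, np.logspace(-8.5, -5.5, 6), 5)
        pts = [
            (r.concentration, ephys.modification_result(r.trace, spec.e_na).m_percent)
            for r in records
        ]
        fit = ephys.fit_hill(pts)
        assert fit.ec50_ == pytest.approx(1e-7, rel=0.20)


class TestSequences:
    def test_planted_eight_differences_two_nonsynonymous(self, sequence_spec):
        sus, res = synthgen.generate_strain_pair(sequence_spec)
        cmp = kdrseq.compare_cds(sus, res)
        assert cmp.n_differences == 8
        assert cmp.n_nonsynonymous == 2
        assert {(d.codon_number, d.aa_a, d.aa_b) for d in cmp.nonsynonymous} == {
            (410, "V", "L"),
            (1534, "F", "C"),
        }

    def test_empty_change_lists_identity(self):
        spec = synthgen.SequenceSimSpec(syn_positions=(), nonsyn_changes=(), genotype_config={})
        sus, res = synthgen.generate_strain_pair(spec)
        assert sus.seq == res.seq

    def test_roundtrip_recovers_planted_changes(self):
        rng = np.random.default_rng(8)
        template = synthgen.default_template_cds()
        # restrict to codons that admit a single-base synonymous change
        eligible = []
        for res in range(2, 1500):
            codon = template[(res - 1) * 3 : res * 3]
            try:
                synthgen.synonymous_substitution(codon, rng)
                eligible.append(res)
            except ValueError:
                continue
        for _ in range(5):
            syn = tuple(sorted(rng.choice(eligible, size=4, replace=False)))
            spec = synthgen.SequenceSimSpec(
                template_cds=template, syn_positions=syn,
                nonsyn_changes=((410, "GTA", "TTA"),), genotype_config={},
                seed=int(rng.integers(1 << 20)),
            )
            sus, res = synthgen.generate_strain_pair(spec)
            cmp = kdrseq.compare_cds(sus, res)
            assert sorted({d.codon_number for d in cmp.differences}) == sorted(
                set(syn) | {410}
            )
            assert cmp.n_nonsynonymous == 1

    def test_unsplittable_codon_rejected(self):
        # ATG has no single-base synonymous neighbour
        template = list(synthgen.default_template_cds())
        template[(200 - 1) * 3 : 200 * 3] = "ATG"
        spec = synthgen.SequenceSimSpec(
            template_cds="".join(template), syn_positions=(200,),
            nonsyn_changes=(), genotype_config={},
        )
        with pytest.raises(ValueError, match="synonymous"):
            synthgen.generate_strain_pair(spec)

    def test_synonymous_requested_change_that_alters_aa_rejected(self):
        with pytest.raises(ValueError, match="does not alter"):
            synthgen.SequenceSimSpec(nonsyn_changes=((410, "GTA", "GTC"),), genotype_config={})

    def test_wild_codon_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expected wild codon"):
            synthgen.SequenceSimSpec(nonsyn_changes=((410, "TTC", "TGC"),), genotype_config={})


class TestGenotypePanel:
    def test_heterozygote_iupac_codon(self, sequence_spec):
        panel = synthgen.generate_genotype_panel(sequence_spec)
        # individuals 4-7 are het at 410: GTA/TTA -> KTA
        het_seq = panel.individuals["ind04"]
        assert het_seq[409 * 3 : 410 * 3] == "KTA"
        call = kdrseq.call_codon(het_seq, 410)
        assert call.zygosity == "het"
        assert call.amino_acids == ("L", "V")

    def test_planted_frequencies(self, sequence_spec):
        panel = synthgen.generate_genotype_panel(sequence_spec)
        assert kdrseq.allele_frequency(panel, 410).percent == 50.0
        assert kdrseq.allele_frequency(panel, 1534).percent == 100.0

    def test_all_hom_wild_zero_frequency(self):
        spec = synthgen.SequenceSimSpec(
            genotype_config={410: ("hom_wild",) * 10, 1534: ("hom_wild",) * 10}
        )
        panel = synthgen.generate_genotype_panel(spec)
        assert kdrseq.allele_frequency(panel, 410).percent == 0.0

    def test_unknown_zygosity_rejected(self):
        with pytest.raises(ValueError, match="zygosity"):
            synthgen.SequenceSimSpec(genotype_config={410: ("hemizygous",) * 10})

    def test_config_must_cover_all_individuals(self):
        with pytest.raises(ValueError, match="covers"):
            synthgen.SequenceSimSpec(genotype_config={410: ("het",) * 7})
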