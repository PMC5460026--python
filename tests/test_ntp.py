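import numpy as np
import pandas as pd
import pytest

from sigrobust import SignatureGeneSet, build_templates, ntp_classify, region_concordance
from sigrobust.ntp import calls_to_frame


def labelled_signature(markers_per_subtype, subtypes=("S1", "S2")):
    genes, subtype_of = [], {}
    for s in subtypes:
        for j in range(markers_per_subtype):
            g = f"{s}_G{j}"
            genes.append(g)
            subtype_of[g] = (s,)
    return SignatureGeneSet("demo", genes, subtype_of)


def synthetic_cohort(templates, truth, noise_sd, seed, extra_genes=0):
    """Samples drawn as template-plus-noise over the template gene union,
    optionally padded with unrelated background genes."""
    rng = np.random.default_rng(seed)
    x = templates.vectors[truth].T + rng.normal(
        0, noise_sd, (len(truth), len(templates.genes))).T
    frame = pd.DataFrame(x, index=templates.genes,
                         columns=[f"smp{i}" for i in range(len(truth))])
    if extra_genes:
        bg = pd.DataFrame(
            rng.normal(0, 1, (extra_genes, len(truth))),
            index=[f"BG{i}" for i in range(extra_genes)],
            columns=frame.columns,
        )
        frame = pd.concat([frame, bg])
    return frame


class TestBuildTemplates:
    def test_two_subtypes(self):
        sig = labelled_signature(2)
        tpl = build_templates(sig)
        assert tpl.subtypes == ["S1", "S2"]
        assert tpl.vectors.sum(axis=1).tolist() == [2.0, 2.0]

    def test_gene_in_two_subtypes_in_both_vectors(self):
        sig = SignatureGeneSet(
            "multi", ["G1", "G2", "G3"],
            {"G1": ("A", "B"), "G2": ("A",), "G3": ("B",)},
        )
        tpl = build_templates(sig)
        g1 = tpl.genes.index("G1")
        assert tpl.vectors[0, g1] == tpl.vectors[1, g1] == 1.0

    def test_unlabelled_gene_is_error(self):
        sig = SignatureGeneSet("bad", ["G1", "G2"], {"G1": ("A",)})
        with pytest.raises(ValueError, match="without subtype"):
            build_templates(sig)

    def test_five_subtype_classifier(self):
        sig = labelled_signature(3, subtypes=tuple(f"C{i}" for i in "ABCDE"))
        assert len(build_templates(sig).subtypes) == 5


class TestClassify:
    def test_sample_equal_to_template(self):
        tpl = build_templates(labelled_signature(3))
        m = synthetic_cohort(tpl, [0, 1], noise_sd=0.0, seed=0)
        calls = ntp_classify(m, tpl, n_resamples=50, seed=0)
        assert [c.label for c in calls] == ["S1", "S2"]
        assert calls[0].distance == pytest.approx(0.0)

    def test_hand_computed_cosine(self):
        """2 subtypes x 2 markers, sample (2,2,-1,-1): cosine to (1,1,0,0)
        is 4/(sqrt(10)*sqrt(2)), so distance 1 - 0.894 = 0.1056."""
        tpl = build_templates(labelled_signature(2))
        m = pd.DataFrame({"s": [2.0, 2.0, -1.0, -1.0]}, index=tpl.genes)
        calls = ntp_classify(m, tpl, n_resamples=50, seed=0)
        assert calls[0].label == "S1"
        assert calls[0].distance == pytest.approx(1 - 4 / np.sqrt(20), abs=1e-9)

    def test_orthogonal_sample_ties_to_first_subtype(self):
        tpl = build_templates(labelled_signature(2))
        # equal loading on both templates -> equal distances; tie-break by
        # declared subtype order
        m = pd.DataFrame({"s": [1.0, 1.0, 1.0, 1.0]}, index=tpl.genes)
        calls = ntp_classify(m, tpl, n_resamples=200, seed=0)
        assert calls[0].label == "S1"

    def test_accuracy_improves_as_noise_vanishes(self):
        tpl = build_templates(labelled_signature(10, subtypes=("A", "B", "C")))
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 3, 60)
        accs = []
        for noise in (2.0, 0.5, 0.01):
            m = synthetic_cohort(tpl, truth, noise_sd=noise, seed=1)
            calls = ntp_classify(m, tpl, n_resamples=50, seed=0)
            accs.append(np.mean(
                [c.label == tpl.subtypes[t] for c, t in zip(calls, truth)]))
        assert accs == sorted(accs)
        assert accs[-1] == 1.0

    def test_p_values_deterministic_and_valid(self):
        tpl = build_templates(labelled_signature(5))
        m = synthetic_cohort(tpl, [0, 1, 0, 1], noise_sd=0.3, seed=2,
                             extra_genes=50)
        a = ntp_classify(m, tpl, n_resamples=200, seed=9)
        b = ntp_classify(m, tpl, n_resamples=200, seed=9)
        assert [c.p_value for c in a] == [c.p_value for c in b]
        for c in a:
            assert 0 < c.p_value <= 1
            assert c.fdr >= c.p_value or np.isclose(c.fdr, c.p_value)
            assert c.significant == (c.fdr < 0.2)

    def test_invariant_to_gene_order_and_extra_genes(self):
        tpl = build_templates(labelled_signature(5))
        m = synthetic_cohort(tpl, [0, 1, 1], noise_sd=0.2, seed=3)
        base = ntp_classify(m, tpl, n_resamples=100, seed=0)
        shuffled = m.sample(frac=1.0, random_state=0)
        out = ntp_classify(shuffled, tpl, n_resamples=100, seed=0)
        assert [c.label for c in base] == [c.label for c in out]
        assert [c.distance for c in base] == pytest.approx(
            [c.distance for c in out])

    def test_too_few_matched_markers_is_error(self):
        tpl = build_templates(labelled_signature(2))
        m = pd.DataFrame({"s": [1.0], "t": [2.0]}, index=["S1_G0"])
        with pytest.raises(ValueError, match="<2 marker genes"):
            ntp_classify(m, tpl, n_resamples=10, seed=0)


class TestRegionConcordance:
    def make_calls(self, labels_by_sample):
        tpl = build_templates(labelled_signature(2))
        calls = []
        from sigrobust.ntp import SubtypeCall
        for s, lab in labels_by_sample.items():
            calls.append(SubtypeCall(s, lab, 0.1, 0.01, 0.02, True))
        return calls

    def annotation(self, samples):
        return pd.DataFrame(
            {
                "patient_id": [s.split("_")[0] for s in samples],
                "region": [s.split("_")[1] for s in samples],
            },
            index=pd.Index(list(samples), name="sample_id"),
        )

    def test_pairwise_concordant(self):
        labels = {"A_CT": "S1", "A_IF": "S1", "B_CT": "S1", "B_IF": "S2"}
        calls = self.make_calls(labels)
        table = region_concordance(calls, self.annotation(labels),
                                   regions=("CT", "IF"))
        row = table.rows[("CT", "IF")]
        assert row["n_concordant"] == 1
        assert row["frac_concordant"] == 0.5

    def test_no_overlap_patient(self):
        labels = {"A_CT": "S1", "A_IF": "S2", "A_LN": "S3",
                  "B_CT": "S1", "B_IF": "S1", "B_LN": "S2"}
        calls = self.make_calls(labels)
        table = region_concordance(calls, self.annotation(labels))
        full = table.rows[("CT", "IF", "LN")]
        assert full["n_concordant"] == 0
        assert full["n_no_overlap"] == 1  # only patient A

    def test_missing_call_is_error(self):
        labels = {"A_CT": "S1", "B_CT": "S1", "B_IF": "S1"}
        calls = self.make_calls(labels)
        ann = self.annotation({"A_CT": 0, "A_IF": 0, "B_CT": 0, "B_IF": 0})
        with pytest.raises(ValueError, match="missing call"):
            region_concordance(calls, ann, regions=("CT", "IF"))

    def test_calls_frame_schema(self):
        calls = self.make_calls({"A_CT": "S1"})
        frame = calls_to_frame(calls)
        assert list(frame.columns) == [
            "label", "distance", "p_value", "fdr", "significant"]
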