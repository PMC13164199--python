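"""Composite-index construction: internal-standard normalization,
monomer/dimer deduplication, PLS latent-score indices and projection."""

import numpy as np
import pandas as pd
import pytest

from chemocal.containers import INTERNAL_STANDARD, PeakTable
from chemocal.index import (
    build_index,
    deduplicate_forms,
    normalize_to_internal_standard,
    project_index,
)
from chemocal.synthetic import StudyDesign, VolatileGeneratorConfig, generate_peak_table


def _tiny_table(volumes: dict, is_volume=1.0) -> PeakTable:
    """volumes: {(compound, cas, form): {(sample, rep): volume}}"""
    rows = []
    keys = set()
    for (compound, cas, form), cells in volumes.items():
        for (sample, rep), vol in cells.items():
            keys.add((sample, rep))
            rows.append(
                dict(compound=compound, cas=cas, form=form, compound_class="test",
                     sample=sample, replicate=rep, volume=vol)
            )
    for sample, rep in sorted(keys):
        rows.append(
            dict(compound=INTERNAL_STANDARD, cas="IS", form="M",
                 compound_class="internal_standard", sample=sample,
                 replicate=rep, volume=is_volume)
        )
    return PeakTable(pd.DataFrame(rows))


class TestNormalization:
    def test_injection_factor_cancels_exactly(self, design):
        cfg = VolatileGeneratorConfig(replicate_cv=0.0, injection_effect_sd=0.0)
        table = generate_peak_table(design, cfg)
        # double every volume of one replicate (an injection effect)
        data = table.data.copy()
        mask = (data["sample"] == "P4") & (data["replicate"] == 2)
        data.loc[mask, "volume"] *= 2.0
        perturbed = PeakTable(data)
        np.testing.assert_allclose(
            normalize_to_internal_standard(perturbed).data["volume"].to_numpy(),
            normalize_to_internal_standard(table).data["volume"].to_numpy(),
            rtol=1e-12,
        )

    def test_unit_standard_leaves_volumes_unchanged(self):
        table = _tiny_table(
            {("x", "c1", "M"): {("A", 1): 5.0, ("A", 2): 7.0, ("B", 1): 2.0, ("B", 2): 3.0}}
        )
        out = normalize_to_internal_standard(table)
        assert INTERNAL_STANDARD not in set(out.data["compound"])
        np.testing.assert_allclose(out.data["volume"], [5.0, 7.0, 2.0, 3.0])

    def test_replicate_cv_shrinks_under_dominant_injection_noise(self, design):
        table = generate_peak_table(design, VolatileGeneratorConfig(), seed=11)

        def mean_cv(tab, compounds):
            sub = tab.data[tab.data["compound"].isin(compounds)]
            g = sub.groupby(["compound", "sample"])["volume"]
            return (g.std(ddof=1) / g.mean()).groupby("compound").mean()

        rise = [
            c for c in table.data["compound"].unique()
            if c.split("_")[0] in ("aldehyde", "acid", "furan") and not c.endswith("-D")
        ]
        before = mean_cv(table, rise)
        after = mean_cv(normalize_to_internal_standard(table), rise)
        assert (after < before).all()

    def test_missing_standard_names_replicate(self):
        table = _tiny_table(
            {("x", "c1", "M"): {("A", 1): 5.0, ("A", 2): 7.0, ("B", 1): 2.0, ("B", 2): 3.0}}
        )
        data = table.data[
            ~((table.data["compound"] == INTERNAL_STANDARD)
              & (table.data["sample"] == "B") & (table.data["replicate"] == 2))
        ]
        with pytest.raises(ValueError, match="'B', 2"):
            normalize_to_internal_standard(PeakTable(data))


class TestDeduplication:
    def test_stability_ratio_prefers_intense_reproducible_form(self):
        # M: mean 100, ~5% replicate CV; D: mean 40, ~20% CV -> keep M
        cells_m = {("A", r): v for r, v in enumerate([95.0, 100.0, 105.0], 1)}
        cells_m |= {("B", r): v for r, v in enumerate([98.0, 100.0, 102.0], 1)}
        cells_d = {("A", r): v for r, v in enumerate([30.0, 40.0, 50.0], 1)}
        cells_d |= {("B", r): v for r, v in enumerate([32.0, 40.0, 48.0], 1)}
        table = _tiny_table({("x", "c1", "M"): cells_m, ("x-D", "c1", "D"): cells_d})
        dedup, log = deduplicate_forms(table)
        assert set(dedup.data[dedup.data["cas"] == "c1"]["form"]) == {"M"}
        assert log.iloc[0]["kept_form"] == "M"

    def test_identical_forms_tie_to_monomer(self):
        cells = {("A", 1): 10.0, ("A", 2): 10.0, ("B", 1): 20.0, ("B", 2): 20.0}
        table = _tiny_table({("x", "c1", "M"): cells, ("x-D", "c1", "D"): dict(cells)})
        dedup, log = deduplicate_forms(table)
        assert log.iloc[0]["kept_form"] == "M"

    def test_generator_pairs_have_perfect_profile_correlation(self, design):
        cfg = VolatileGeneratorConfig(replicate_cv=0.0, injection_effect_sd=0.0)
        table = normalize_to_internal_standard(generate_peak_table(design, cfg))
        _, log = deduplicate_forms(table)
        assert len(log) > 0
        np.testing.assert_allclose(log["md_spearman"], 1.0, atol=1e-12)

    def test_at_most_one_row_per_cas(self, design):
        table = normalize_to_internal_standard(
            generate_peak_table(design, VolatileGeneratorConfig())
        )
        dedup, _ = deduplicate_forms(table)
        assert dedup.data.groupby("cas")["form"].nunique().eq(1).all()


class TestCompositeIndex:
    @pytest.fixture
    def dedup_table(self, design):
        table = generate_peak_table(design, VolatileGeneratorConfig())
        dedup, _ = deduplicate_forms(normalize_to_internal_standard(table))
        return dedup

    def _months_response(self, design):
        samples = design.processed_labels
        return samples, pd.Series(
            [design.months_of(s) for s in samples], index=samples, dtype=float
        )

    def test_recovers_storage_rank_order(self, design, dedup_table):
        samples, months = self._months_response(design)
        markers = [c for c in dedup_table.sample_means().columns][:40]
        composite = build_index(dedup_table, samples, months, markers)
        rho = composite.values.loc[samples].corr(months, method="spearman")
        assert rho == pytest.approx(1.0)

    def test_orientation_absorbs_sign_reflection(self, design, dedup_table):
        """Negating the marker matrix flips the latent direction; the
        orientation convention restores the same index."""
        from chemocal.pls import fit_pls1

        samples, months = self._months_response(design)
        markers = list(dedup_table.sample_means().columns[:20])
        X = dedup_table.sample_means().loc[samples, markers].to_numpy()
        y = months.to_numpy()

        def oriented_scores(M):
            model = fit_pls1(M, y, 1, scale_x=True)
            t = model.T[:, 0]
            return t * (np.sign(np.corrcoef(t, y)[0, 1]) or 1.0)

        np.testing.assert_allclose(
            oriented_scores(X), oriented_scores(-X), atol=1e-10
        )

    def test_constant_response_rejected(self, design, dedup_table):
        samples = design.processed_labels
        flat = pd.Series(1.0, index=samples)
        with pytest.raises(ValueError, match="constant"):
            build_index(dedup_table, samples, flat, ["aldehyde_01"])

    def test_projection_consistency(self, design, dedup_table):
        samples, months = self._months_response(design)
        markers = list(dedup_table.sample_means().columns[:30])
        composite = build_index(dedup_table, samples, months, markers)
        projected = project_index(composite, dedup_table, samples)
        np.testing.assert_allclose(projected, composite.values, atol=1e-10)

    def test_sample_at_training_means_scores_zero(self, design, dedup_table):
        samples, months = self._months_response(design)
        markers = list(dedup_table.sample_means().columns[:30])
        composite = build_index(dedup_table, samples, months, markers)
        means = dedup_table.sample_means().loc[samples, markers].mean()
        center = pd.DataFrame([means], index=["center"])
        assert composite.project(center).iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_missing_marker_column_rejected(self, design, dedup_table):
        samples, months = self._months_response(design)
        markers = list(dedup_table.sample_means().columns[:10])
        composite = build_index(dedup_table, samples, months, markers)
        bad = dedup_table.sample_means().loc[samples].drop(columns=markers[:1])
        with pytest.raises(KeyError, match=markers[0]):
            composite.project(bad)

    def test_index_invariant_to_per_replicate_scaling(self, design):
        table = generate_peak_table(design, VolatileGeneratorConfig(), seed=5)
        data = table.data.copy()
        mask = (data["sample"] == "P29") & (data["replicate"] == 1)
        data.loc[mask, "volume"] *= 7.5
        scaled = PeakTable(data)
        samples = design.processed_labels
        months = pd.Series([design.months_of(s) for s in samples], index=samples)

        def index_of(tab):
            dedup, _ = deduplicate_forms(normalize_to_internal_standard(tab))
            markers = list(dedup.sample_means().columns[:25])
            return build_index(dedup, samples, months, markers).values

        np.testing.assert_allclose(index_of(table), index_of(scaled), rtol=1e-10)
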