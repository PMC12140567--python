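"""Atlas loading and cohort I/O: validation, canonical ordering, round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import build_cohort
from mplexcov.atlas import RoiAtlas, load_atlas, synthetic_atlas
from mplexcov.cohort import read_cohort, split_by_group, write_cohort


class TestAtlas:
    @pytest.mark.parametrize(
        "name,n", [("dk68", 68), ("destrieux148", 148)]
    )
    def test_bundled_atlases(self, name, n):
        atlas = load_atlas(name)
        assert atlas.n_regions == n
        assert len(set(atlas.regions)) == n
        halves = [atlas.hemisphere(r) for r in atlas.regions]
        assert halves.count("lh") == n // 2 and halves.count("rh") == n // 2

    def test_dk_lobe_map_covers_all_regions(self):
        atlas = load_atlas("dk68")
        assert all(atlas.lobe(r) for r in atlas.regions)
        assert atlas.lobe("lh-entorhinal") == "temporal"
        assert atlas.lobe("rh-rostralanteriorcingulate") == "cingulate"

    def test_duplicate_regions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RoiAtlas(name="bad", regions=("lh-a", "lh-a"))

    def test_unknown_atlas_name(self):
        with pytest.raises(ValueError, match="unknown atlas"):
            load_atlas("aal")


class TestCohortIO:
    def _write(self, cohort, tmp_path, ext="tsv"):
        paths = {m: tmp_path / f"{m}.{ext}" for m in cohort.modalities}
        write_cohort(cohort, paths)
        return paths

    @pytest.mark.parametrize("ext", ["tsv", "csv"])
    def test_round_trip_bit_identical(self, atlas4, tmp_path, ext):
        cohort = build_cohort(atlas4, 3)
        paths = self._write(cohort, tmp_path, ext)
        back = read_cohort(paths, atlas4)
        assert back.n_subjects == 3 and back.modalities == cohort.modalities
        for m in cohort.modalities:
            pd.testing.assert_frame_equal(back.roi[m], cohort.roi[m])
        pd.testing.assert_frame_equal(back.covariates, cohort.covariates)

    def test_smallest_valid_cohort(self, atlas4, tmp_path):
        cohort = build_cohort(atlas4, 3)
        back = read_cohort(self._write(cohort, tmp_path), atlas4)
        assert back.atlas.n_regions == 4
        assert len(back.modalities) == 2

    def test_shuffled_columns_are_canonicalized(self, atlas4, tmp_path):
        cohort = build_cohort(atlas4, 4)
        paths = self._write(cohort, tmp_path)
        # rewrite one file with region columns reversed
        df = pd.read_csv(paths["CTH"], sep="\t")
        shuffled = df[
            ["subject_id", "group", "age", "sex", "education"]
            + list(atlas4.regions)[::-1]
        ]
        shuffled.to_csv(paths["CTH"], sep="\t", index=False)
        back = read_cohort(paths, atlas4)
        assert tuple(back.roi["CTH"].columns) == atlas4.regions
        pd.testing.assert_frame_equal(back.roi["CTH"], cohort.roi["CTH"])

    def test_missing_region_column_named_in_error(self, atlas4, tmp_path):
        cohort = build_cohort(atlas4, 3)
        paths = self._write(cohort, tmp_path)
        df = pd.read_csv(paths["FDG"], sep="\t").drop(columns=["lh-entorhinal"])
        df.to_csv(paths["FDG"], sep="\t", index=False)
        with pytest.raises(ValueError, match="lh-entorhinal"):
            read_cohort(paths, atlas4)

    def test_subject_missing_from_one_modality(self, atlas4, tmp_path):
        cohort = build_cohort(atlas4, 4)
        paths = self._write(cohort, tmp_path)
        df = pd.read_csv(paths["FDG"], sep="\t").iloc[1:]
        df.to_csv(paths["FDG"], sep="\t", index=False)
        with pytest.raises(ValueError, match="not shared"):
            read_cohort(paths, atlas4)

    def test_duplicate_subject_rejected(self, atlas4, tmp_path):
        cohort = build_cohort(atlas4, 3)
        paths = self._write(cohort, tmp_path)
        df = pd.read_csv(paths["CTH"], sep="\t")
        pd.concat([df, df.iloc[[0]]]).to_csv(paths["CTH"], sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(paths, atlas4)

    def test_non_numeric_roi_cell(self, atlas4, tmp_path):
        cohort = build_cohort(atlas4, 3)
        paths = self._write(cohort, tmp_path)
        df = pd.read_csv(paths["CTH"], sep="\t")
        df["lh-fusiform"] = df["lh-fusiform"].astype(object)
        df.loc[0, "lh-fusiform"] = "2.4mm"
        df.to_csv(paths["CTH"], sep="\t", index=False)
        with pytest.raises(ValueError, match="non-numeric"):
            read_cohort(paths, atlas4)

    def test_text_sex_coding(self, atlas4, tmp_path):
        cohort = build_cohort(atlas4, 4)
        paths = self._write(cohort, tmp_path)
        for p in paths.values():
            df = pd.read_csv(p, sep="\t")
            df["sex"] = ["M", "F", "M", "F"]
            df.to_csv(p, sep="\t", index=False)
        back = read_cohort(paths, atlas4)
        assert list(back.covariates["sex"]) == [1, 0, 1, 0]


class TestSplitByGroup:
    def test_partition_sizes(self, atlas4):
        cohort = build_cohort(atlas4, 9, groups=("bvFTD", "PPA", "bvFTD"))
        parts = split_by_group(cohort, ["bvFTD", "PPA"])
        sizes = {g: t.n_subjects for g, t in parts.items()}
        assert sum(sizes.values()) == 9
        assert all(
            set(t.covariates["group"]) == {g} for g, t in parts.items()
        )

    def test_single_group_excludes_others(self, atlas4):
        cohort = build_cohort(atlas4, 6, groups=("A", "B"))
        parts = split_by_group(cohort, ["A"])
        assert set(parts) == {"A"}
        assert parts["A"].n_subjects == 3

    def test_unknown_label_errors(self, atlas4):
        cohort = build_cohort(atlas4, 4, groups=("A",))
        with pytest.raises(ValueError, match="AD"):
            split_by_group(cohort, ["AD"])


def test_region_permutation_equivariance_end_to_end(tmp_path):
    """Permuting input region columns permutes all downstream matrices."""
    from mplexcov.measures import compute_measures
    from mplexcov.networks import build_supra, group_correlation, threshold_binarize
    from mplexcov.residualize import residualize

    atlas = synthetic_atlas(6)
    cohort = build_cohort(atlas, 12, seed=7)
    perm = np.array([3, 0, 5, 1, 4, 2])
    atlas_p = RoiAtlas(name="perm", regions=tuple(atlas.regions[i] for i in perm))
    cohort_p = build_cohort(atlas, 12, seed=7)
    cohort_p.atlas = atlas_p
    cohort_p.roi = {
        m: cohort.roi[m][list(atlas_p.regions)] for m in cohort.modalities
    }

    def nodal_mpc_by_region(c):
        layers = []
        for m in c.modalities:
            res, _ = residualize(c, m)
            lw = group_correlation(res, m)
            layers.append(threshold_binarize(lw, 0.5))
        net = build_supra(layers, threshold=0.5)
        p = compute_measures(net).nodal_mpc
        return dict(zip(c.atlas.regions, p))

    assert nodal_mpc_by_region(cohort) == pytest.approx(
        nodal_mpc_by_region(cohort_p)
    )
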