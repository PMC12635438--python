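import numpy as np
import pandas as pd
import pytest

from mitoscape import (
    LabeledVolume,
    VoxelSpacing,
    assign_compartment,
    cell_analysis,
    filter_by_volume,
    phantoms,
    picture_analysis,
    process_analysis,
)
from mitoscape.distance import DistanceMap


@pytest.fixture(scope="module")
def rgc_result(rgc, rgc_annotation):
    return cell_analysis(rgc.mito, rgc_annotation, rgc_annotation.soma_dist, rgc.cell.spacing)


class TestAssignCompartment:
    def test_center_inside_soma(self, rgc_annotation, rgc_result):
        soma_rows = rgc_result.element_table[rgc_result.element_table["compartment"] == 1]
        assert len(soma_rows) == 2  # the two punctae placed in the soma

    def test_spanning_element_takes_center_compartment(self, iso01):
        # dumbbell: most of the skeleton path sits in compartment 2, so the
        # barycenter (and hence the element) lands in the process
        comp = np.zeros((7, 7, 30), np.int32)
        comp[:, :, :10] = 1
        comp[:, :, 10:] = 2
        mito = np.zeros((7, 7, 30), bool)
        mito[3, 3, 6:26] = True  # 6 voxels in soma, 14 in process
        dist = DistanceMap(
            np.zeros(comp.shape), comp > 0, np.zeros_like(mito), np.zeros(comp.shape, bool), iso01
        )
        res = cell_analysis(mito, LabeledVolume(comp, iso01), dist, iso01)
        assert res.element_table["compartment"].tolist() == [2]

    def test_center_on_background_is_unassigned(self, iso01):
        comp = np.zeros((7, 7, 20), np.int32)
        comp[:, :, :5] = 1
        mito = np.zeros((7, 7, 20), bool)
        mito[3, 3, 10:15] = True  # entirely outside the cell mask
        dist = DistanceMap(
            np.zeros(comp.shape), comp > 0, np.zeros_like(mito), np.zeros(comp.shape, bool), iso01
        )
        res = cell_analysis(
            mito, LabeledVolume(comp, iso01), dist, iso01, clip_to_cell=False
        )
        assert res.qc["unassigned_elements"] == 1
        assert res.compartment_table["n_elements"].sum() == 0

    def test_direct_lookup(self, iso01):
        comp = np.zeros((5, 5, 5), np.int32)
        comp[2] = 3
        assert assign_compartment((2, 1, 1), comp) == 3
        assert assign_compartment((0, 0, 0), comp) == 0


class TestCellAnalysis:
    def test_all_mito_in_soma_density(self, iso01):
        comp = np.zeros((9, 9, 9), np.int32)
        comp[1:8, 1:8, 1:8] = 1
        mito = np.zeros((9, 9, 9), bool)
        mito[3:5, 3:5, 3:5] = True
        dist = DistanceMap(
            np.zeros(comp.shape), comp > 0, np.zeros_like(mito), np.zeros(comp.shape, bool), iso01
        )
        res = cell_analysis(mito, LabeledVolume(comp, iso01), dist, iso01)
        row = res.compartment_table.iloc[0]
        assert row["mito_density"] == pytest.approx(8 / 343)
        assert 0 <= row["mito_density"] <= 1

    def test_rgc_element_counts_and_classes(self, rgc, rgc_result):
        table = rgc_result.element_table
        assert len(table) == len(rgc.truth)
        merged = table.merge(rgc.truth, on="element_id", suffixes=("", "_t"))
        assert (merged["class"] == merged["class_t"]).all()
        # compartment recovery: punctae in soma (1), rods in apical (2) / basal (3)
        by_comp = merged.groupby("compartment")["element_id"].count().to_dict()
        assert by_comp == {1: 2, 2: 1, 3: 1}

    def test_voxelwise_volume_conservation(self, rgc, rgc_result):
        total = rgc.mito.grid.sum() * rgc.mito.spacing.voxel_volume
        assert rgc_result.compartment_table["mito_volume_um3"].sum() == pytest.approx(total)

    def test_fractions_sum_to_one_where_elements_exist(self, rgc_result):
        t = rgc_result.compartment_table
        nz = t[t["n_elements"] > 0]
        sums = nz[["frac_punctae", "frac_rods", "frac_networks"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_shape_mismatch_raises(self, iso01):
        comp = np.ones((4, 4, 4), np.int32)
        dist = DistanceMap(
            np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool),
            np.zeros((4, 4, 4), bool), iso01,
        )
        with pytest.raises(ValueError):
            cell_analysis(np.zeros((5, 5, 5), bool), LabeledVolume(comp, iso01), dist, iso01)


def two_cell_scene():
    """Two box cells with ball somas and a couple of mitochondria each."""
    sp = VoxelSpacing(0.1, 0.1, 0.1)
    shape = (20, 20, 46)
    cells = np.zeros(shape, np.int32)
    cells[4:16, 4:16, 2:20] = 1
    cells[4:16, 4:16, 26:44] = 2
    somas = np.zeros(shape, np.int32)
    somas[6:14, 6:14, 3:11] = 1
    somas[6:14, 6:14, 27:35] = 2
    mito = np.zeros(shape, bool)
    zz, yy, xx = np.mgrid[0:20, 0:20, 0:46]
    mito[(zz - 9) ** 2 + (yy - 9) ** 2 + (xx - 6) ** 2 <= 9] = True  # ball, cell 1 soma
    mito[9, 9, 13:19] = True  # thin rod, cell 1 process region
    mito[(zz - 9) ** 2 + (yy - 9) ** 2 + (xx - 30) ** 2 <= 9] = True  # ball, cell 2 soma
    return (
        LabeledVolume(cells, sp),
        LabeledVolume(somas, sp),
        LabeledVolume(mito.astype(np.uint8), sp),
    )


class TestPictureAnalysis:
    def test_two_cell_ids_present(self):
        cells, somas, mito = two_cell_scene()
        res = picture_analysis(mito, cells, somas)
        assert sorted(res.compartment_table["cell_id"].unique()) == [1, 2]
        assert sorted(res.element_table["cell_id"].unique()) == [1, 2]

    def test_cropping_invariance_per_cell(self):
        from mitoscape import cell_annotation

        cells, somas, mito = two_cell_scene()
        res = picture_analysis(mito, cells, somas)
        # analyze cell 1 alone in a tight bounding box
        sel = cells.grid == 1
        zs, ys, xs = np.where(sel)
        box = (slice(zs.min(), zs.max() + 1), slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        cell1 = sel[box]
        soma1 = (somas.grid == 1)[box]
        mito1 = mito.as_bool()[box] & cell1
        comp = cell_annotation(cell1, soma1, cells.spacing)
        solo = cell_analysis(mito1, comp, comp.soma_dist, cells.spacing, cell_id=1)
        full_rows = res.element_table[res.element_table["cell_id"] == 1].reset_index(drop=True)
        solo_rows = solo.element_table.reset_index(drop=True)
        for col in ("class", "length_um", "volume_um3", "surface_um2", "sphericity",
                    "compartment", "distance_from_soma_um"):
            assert list(full_rows[col]) == pytest.approx(list(solo_rows[col])) \
                if full_rows[col].dtype.kind == "f" else (full_rows[col] == solo_rows[col]).all()

    def test_no_cells_empty_tables(self, iso01):
        empty = LabeledVolume(np.zeros((5, 5, 5), np.int32), iso01)
        res = picture_analysis(np.zeros((5, 5, 5), bool), empty, empty)
        assert len(res.compartment_table) == 0 and len(res.element_table) == 0

    def test_extracellular_mito_reported(self):
        cells, somas, mito = two_cell_scene()
        stray = mito.grid.astype(bool).copy()
        stray[0, 0, 22] = True  # between the two cells
        res = picture_analysis(stray, cells, somas)
        assert res.qc["extracellular_mito_voxels"] == 1


class TestProcessAnalysis:
    def make_tube_process(self):
        sp = VoxelSpacing(0.1, 0.1, 0.1)
        shape = (9, 9, 110)
        comp = np.zeros(shape, np.int32)
        zz, yy = np.mgrid[0:9, 0:9]
        disk = (zz - 4) ** 2 + (yy - 4) ** 2 <= 4
        comp[:, :, :5] = np.where(disk[:, :, None], 1, 0)  # soma stump
        comp[:, :, 5:105] = np.where(disk[:, :, None], 2, 0)  # 10 µm process
        vals = np.full(shape, np.nan)
        for x in range(shape[2]):
            vals[:, :, x] = np.where(disk, max(x - 4, 0) * 0.1, np.nan)
        dist = DistanceMap(vals, comp > 0, comp == 1, np.zeros(shape, bool), sp)
        return comp, dist, sp

    def test_flat_tube_profile_and_exact_conservation(self):
        comp, dist, sp = self.make_tube_process()
        mito = np.zeros(comp.shape, bool)
        prof = process_analysis(LabeledVolume(comp, sp), mito, dist, sp, bin_um=0.5, labels=[2])
        assert (prof["mito_volume_um3"] == 0).all()
        tube_vol = (comp == 2).sum() * sp.voxel_volume
        assert prof["process_volume_um3"].sum() == pytest.approx(tube_vol, abs=1e-12)
        inner = prof["process_volume_um3"].iloc[1:-1]
        assert inner.max() == pytest.approx(inner.min(), rel=0.2)  # flat within discretization

    def test_point_mass_lands_in_its_bin(self):
        comp, dist, sp = self.make_tube_process()
        mito = np.zeros(comp.shape, bool)
        mito[4, 4, 36] = True  # distance (36-4)*0.1 = 3.2 µm → bin [3.0, 3.5)
        prof = process_analysis(LabeledVolume(comp, sp), mito, dist, sp, bin_um=0.5)
        hot = prof[prof["mito_volume_um3"] > 0]
        assert len(hot) == 1
        assert hot["bin_left_um"].iloc[0] == pytest.approx(3.0)

    def test_single_bin_when_bin_spans_everything(self):
        comp, dist, sp = self.make_tube_process()
        prof = process_analysis(
            LabeledVolume(comp, sp), np.zeros(comp.shape, bool), dist, sp, bin_um=1000.0, labels=[2]
        )
        assert len(prof) == 1

    def test_bin_refinement_resums_exactly(self):
        comp, dist, sp = self.make_tube_process()
        mito = np.zeros(comp.shape, bool)
        mito[4, 4, 30:80] = True
        coarse = process_analysis(LabeledVolume(comp, sp), mito, dist, sp, bin_um=0.5)
        fine = process_analysis(LabeledVolume(comp, sp), mito, dist, sp, bin_um=0.25)
        fine = fine.assign(parent=(fine["bin_left_um"] // 0.5).astype(int))
        resum = fine.groupby(["process", "parent"])[["process_volume_um3", "mito_volume_um3"]].sum()
        for (proc, parent), row in resum.iterrows():
            c = coarse[(coarse["process"] == proc) & (np.isclose(coarse["bin_left_um"], parent * 0.5))]
            assert row["process_volume_um3"] == pytest.approx(
                c["process_volume_um3"].iloc[0], abs=1e-12
            )
            assert row["mito_volume_um3"] == pytest.approx(c["mito_volume_um3"].iloc[0], abs=1e-12)

    def test_arbitrary_reference_distance_map(self, iso01):
        # lysosome-style reference: distance from a blob, applied to a plain mask
        region = np.zeros((9, 9, 30), np.int32)
        region[2:7, 2:7, :] = 1
        from mitoscape import euclidean_dist

        marker = np.zeros(region.shape, bool)
        marker[4, 4, 0] = True
        dist = euclidean_dist(marker, iso01)
        mito = np.zeros(region.shape, bool)
        mito[4, 4, 10:20] = True
        prof = process_analysis(LabeledVolume(region, iso01), mito, dist, iso01, bin_um=0.5)
        assert prof["mito_volume_um3"].sum() == pytest.approx(10 * iso01.voxel_volume)


class TestFilterByVolume:
    def test_boundary_inclusive_semantics(self):
        t = pd.DataFrame({"volume_um3": [0.02, 0.05, 0.30]})
        out = filter_by_volume(t, 0.05)
        assert out["volume_um3"].tolist() == [0.05, 0.30]

    def test_zero_threshold_is_identity(self):
        t = pd.DataFrame({"volume_um3": [0.02, 0.05, 0.30]})
        assert len(filter_by_volume(t, 0.0)) == 3

    def test_infinite_threshold_empties(self):
        t = pd.DataFrame({"volume_um3": [0.02, 0.05, 0.30]})
        assert len(filter_by_volume(t, np.inf)) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_by_volume(pd.DataFrame({"volume_um3": [1.0]}), -0.1)
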