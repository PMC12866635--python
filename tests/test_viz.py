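"""Rendering contracts: point counts, reserved color, selection, export."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

import cellsnv as c
from cellsnv.viz import RESERVED_COLOR, map_colors, read_plot_data

from conftest import matrix_from_columns


@pytest.fixture
def view(small_embedding):
    metrics = pd.DataFrame({
        "barcode": small_embedding.barcodes,
        "n_snvs": np.arange(10),
        "total_nvar": np.arange(10) * 2,
        "total_nref": np.arange(10)[::-1],
        "total_vaf": [0.2, 0.5, 1.0, np.nan, 0.0, 0.3, np.nan, 0.8, 0.9, 0.1],
        "mean_vaf": np.linspace(0, 1, 10),
        "median_vaf": np.linspace(0, 1, 10),
    })
    return c.make_view(small_embedding, metrics)


class TestPlotSet:
    def test_one_point_per_cell(self, view, tmp_path):
        out = tmp_path / "plot.html"
        c.plot_set(view, c.PlotSpec(metric="total_vaf"), out)
        data = read_plot_data(out)
        assert len(data["panels"][0]["points"]) == 10

    def test_undefined_cells_use_reserved_color(self, view):
        doc = c.plot_set(view, c.PlotSpec(metric="total_vaf"))
        points = read_plot_data(doc)["panels"][0]["points"]
        undefined = [p for p in points if p["value"] is None]
        assert len(undefined) == 2
        assert all(p["color"] == RESERVED_COLOR for p in undefined)
        assert all(p["color"] != RESERVED_COLOR for p in points if p["value"] is not None)

    def test_unknown_metric_error_lists_valid_names(self, view):
        with pytest.raises(KeyError, match="total_vaf"):
            c.plot_set(view, c.PlotSpec(metric="bogus"))

    def test_3d_spec_on_2d_only_embedding_errors(self, view):
        emb = view.embedding
        emb2 = c.Embedding(emb.barcodes, {("umap", 2): emb.coords("umap", 2)}, emb.clusters)
        view2 = c.CellView(emb2, view.data)
        with pytest.raises(KeyError):
            c.plot_set(view2, c.PlotSpec(metric="total_vaf", dim=3))

    def test_pure_function_of_inputs(self, view):
        spec = c.PlotSpec(metric="mean_vaf", gradient="blue-white-red")
        assert c.plot_set(view, spec) == c.plot_set(view, spec)

    def test_all_undefined_metric_all_reserved(self, view):
        view.data["total_vaf"] = np.nan
        doc = c.plot_set(view, c.PlotSpec(metric="total_vaf"))
        points = read_plot_data(doc)["panels"][0]["points"]
        assert all(p["color"] == RESERVED_COLOR for p in points)


class TestGradients:
    def test_reserved_color_outside_gradient_range(self):
        for name in ("white-blue", "blue-white-red"):
            values = pd.Series(np.linspace(0, 1, 512))
            colors, _ = map_colors(values, c.PlotSpec(metric="mean_vaf", gradient=name))
            assert RESERVED_COLOR not in colors

    def test_unknown_gradient_rejected(self):
        with pytest.raises(ValueError, match="white-blue"):
            map_colors(pd.Series([0.5]), c.PlotSpec(metric="mean_vaf", gradient="nope"))

    def test_categorical_field_uses_palette(self):
        colors, legend = map_colors(pd.Series(["a", "b", "a"]), c.PlotSpec(metric="cell_type"))
        assert legend["type"] == "categorical"
        assert colors[0] == colors[2] != colors[1]


class TestPlotIndividualSNV:
    def make(self, small_embedding):
        # SNV covered in 3 of 10 cells
        col = [(2, 2), (3, 0), (0, 4)] + [(0, 0)] * 7
        m = matrix_from_columns([col])
        m.cells[:] = small_embedding.barcodes
        view = c.make_view(small_embedding)
        return m, view

    def test_three_panels_reserved_complement(self, small_embedding):
        m, view = self.make(small_embedding)
        doc = c.plot_individual_snv(view, m, m.snvs[0])
        data = read_plot_data(doc)
        assert [p["name"] for p in data["panels"]] == ["N_VAR", "N_REF", "VAF_RNA"]
        counts = [len(p["points"]) for p in data["panels"]]
        assert counts == [10, 10, 10]  # equal across panels
        for panel in data["panels"]:
            reserved = [p for p in panel["points"] if p["color"] == RESERVED_COLOR]
            assert len(reserved) == 7  # complement of the 3 covered cells

    def test_vaf_panel_extremes(self, small_embedding):
        m, view = self.make(small_embedding)
        data = read_plot_data(c.plot_individual_snv(view, m, m.snvs[0]))
        vaf_values = sorted(p["value"] for p in data["panels"][2]["points"] if p["value"] is not None)
        assert vaf_values == [0.0, 0.5, 1.0]

    def test_unknown_snv_errors(self, small_embedding):
        m, view = self.make(small_embedding)
        with pytest.raises(KeyError):
            c.plot_individual_snv(view, m, c.SNVKey("9", 9, "A", "C"))


class TestSelectCells:
    def test_threshold_predicate_excludes_undefined(self, view):
        sub = c.select_cells(view, "total_vaf >= 0.5")
        assert len(sub.embedding.barcodes) == 4  # 0.5, 1.0, 0.8, 0.9; NaN never satisfies
        assert (sub.data["total_vaf"] >= 0.5).all()

    def test_always_true_is_identity(self, view):
        sub = c.select_cells(view, "n_snvs >= 0")
        assert sub.embedding.barcodes == view.embedding.barcodes

    def test_always_false_warns_and_empties(self, view, caplog):
        with caplog.at_level("WARNING"):
            sub = c.select_cells(view, "n_snvs < 0")
        assert len(sub.data) == 0
        assert "matches no cells" in caplog.text

    def test_unknown_field_rejected(self, view):
        with pytest.raises(KeyError, match="unknown field"):
            c.select_cells(view, "bogus_field > 1")

    def test_composes_with_plotting(self, view):
        sub = c.select_cells(view, "total_vaf >= 0.5")
        data = read_plot_data(c.plot_set(sub, c.PlotSpec(metric="total_vaf")))
        assert len(data["panels"][0]["points"]) == 4


class TestStaticOutputs:
    def test_histogram_rasters(self, tmp_path):
        metrics = pd.DataFrame({
            "barcode": list("abcdef"), "n_snvs": [1, 2, 3, 0, 1, 2],
            "total_nvar": [1] * 6, "total_nref": [2] * 6,
            "total_vaf": [0.1, 0.2, 0.9, np.nan, 0.5, 0.4],
            "mean_vaf": [0.1] * 6, "median_vaf": [0.2] * 6,
        })
        summaries, _ = c.summarize_by_group(metrics, ["x", "x", "x", "y", "y", "y"], bins=10)
        paths = c.plot_histograms(summaries, tmp_path)
        assert len(paths) == 6  # one raster per metric
        for p in paths.values():
            assert Image.open(p).size[0] > 0

    def test_export_snapshot(self, view, tmp_path):
        doc = c.plot_set(view, c.PlotSpec(metric="median_vaf"))
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        c.export_snapshot(doc, p1)
        c.export_snapshot(doc, p2)
        assert p1.stat().st_size > 0
        assert Image.open(p1).size == Image.open(p2).size

    def test_export_bad_path_errors(self, view, tmp_path):
        doc = c.plot_set(view, c.PlotSpec(metric="median_vaf"))
        with pytest.raises(Exception):
            c.export_snapshot(doc, tmp_path / "missing_dir" / "x.png")
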