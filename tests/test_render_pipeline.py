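"""SVG rendering and the end-to-end pipeline: counts, colours, determinism."""

import re

import pytest

from conftest import build_scene
from vasculomap import io as aio
from vasculomap.errors import StageError, VasculomapError
from vasculomap.pipeline import PipelineConfig, run_pipeline
from vasculomap.render import RenderStyle, render_svg
from vasculomap.vascular import layout_vascular


@pytest.fixture
def fixture_files(tmp_path):
    scene = build_scene(seed=17, n_paths=40, incomplete_fraction=0.25)
    hierarchy = tmp_path / "hierarchy.tsv"
    paths = tmp_path / "paths.txt"
    with open(hierarchy, "w") as fh:
        aio.write_hierarchy_table(scene["records"], fh)
    with open(paths, "w") as fh:
        aio.write_vascular_paths(scene["paths"], fh)
    return hierarchy, paths, scene


class TestRenderSvg:
    def _render(self, scene, vascular=None):
        return render_svg(
            scene["layouts"], vascular, scene["plan"], scene["regions"], scene["forest"]
        )

    def test_empty_layout_is_valid_svg_with_tile_frames(self, small_scene):
        svg = render_svg(
            {}, None, small_scene["plan"], small_scene["regions"], small_scene["forest"]
        )
        assert svg.startswith('<?xml version="1.0"')
        assert svg.count('class="tile ') == 24
        assert "<polyline" not in svg

    def test_one_rect_per_laid_out_node(self, small_scene):
        svg = self._render(small_scene)
        n_nodes = sum(len(t.rects) for t in small_scene["layouts"].values())
        node_rects = re.findall(r'<rect class="(?:node|micro) ', svg)
        assert len(node_rects) == n_nodes

    def test_vessel_colours_follow_type(self, small_scene):
        vl = layout_vascular(
            small_scene["plan"], small_scene["regions"], small_scene["forest"],
            small_scene["layouts"], small_scene["retained"],
        )
        style = RenderStyle()
        svg = self._render(small_scene, vl)
        for line in svg.splitlines():
            if "<polyline" not in line:
                continue
            assert (style.arterial_colour in line) != (style.venous_colour in line)

    def test_identical_colours_rejected(self):
        with pytest.raises(ValueError):
            RenderStyle(arterial_colour="#111111", venous_colour="#111111")


class TestPipeline:
    def test_two_runs_are_byte_identical(self, fixture_files, tmp_path):
        hierarchy, paths, _ = fixture_files
        cfg = PipelineConfig(hierarchy_file=hierarchy, paths_file=paths, seed=5)
        a = run_pipeline(cfg)
        b = run_pipeline(cfg)
        assert a.svg == b.svg

    def test_out_of_range_max_distance_fails_before_layout(self, fixture_files):
        hierarchy, paths, _ = fixture_files
        cfg = PipelineConfig(hierarchy_file=hierarchy, paths_file=paths, max_distance=17)
        with pytest.raises(VasculomapError):
            run_pipeline(cfg)

    def test_unknown_algorithm_rejected(self, fixture_files):
        hierarchy, paths, _ = fixture_files
        cfg = PipelineConfig(hierarchy_file=hierarchy, paths_file=paths, algorithm="voronoi")
        with pytest.raises(VasculomapError):
            run_pipeline(cfg)

    def test_exclusion_report_matches_incomplete_paths(self, fixture_files, tmp_path):
        hierarchy, paths, scene = fixture_files
        out = tmp_path / "out"
        cfg = PipelineConfig(hierarchy_file=hierarchy, paths_file=paths, out_dir=out)
        result = run_pipeline(cfg)
        assert len(result.excluded) == len(scene["excluded"]) == 10
        rows = (out / "exclusions.tsv").read_text().strip().splitlines()
        assert len(rows) - 1 == 10  # header plus one row per excluded path

    def test_svg_has_no_diagonal_vascular_segments(self, fixture_files):
        """String-level check on every polyline's coordinate list."""
        hierarchy, paths, _ = fixture_files
        result = run_pipeline(
            PipelineConfig(hierarchy_file=hierarchy, paths_file=paths)
        )
        for m in re.finditer(r'points="([^"]+)"', result.svg):
            pts = [tuple(map(float, p.split(","))) for p in m.group(1).split()]
            for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
                assert x1 == x2 or y1 == y2

    @pytest.mark.parametrize("algorithm", ["grid", "slice_dice", "squarified"])
    def test_all_algorithms_run_clean(self, fixture_files, algorithm):
        hierarchy, paths, _ = fixture_files
        result = run_pipeline(
            PipelineConfig(hierarchy_file=hierarchy, paths_file=paths, algorithm=algorithm)
        )
        assert result.vascular.report.ok

    def test_stage_errors_carry_stage_name(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("FMA1\tFMA2\n")
        paths = tmp_path / "p.txt"
        paths.write_text("")
        cfg = PipelineConfig(hierarchy_file=bad, paths_file=paths)
        with pytest.raises(StageError) as err:
            run_pipeline(cfg)
        assert err.value.stage == "parse_hierarchy"
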