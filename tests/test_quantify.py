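"""Image quantification: annotation parsing, segmentation, dot counting, exclusions."""

import json

import numpy as np
import pytest

from agnor_screen import quantify as q, synthetic_data as sd


def _write_labelme(tmp_path, shapes):
    path = tmp_path / "ann.json"
    path.write_text(json.dumps({"shapes": shapes}))
    return path


class TestLoadBoxes:
    def test_corner_order_invariance(self, tmp_path):
        a = _write_labelme(tmp_path, [{"label": "n", "shape_type": "rectangle",
                                       "points": [[10, 20], [40, 60]]}])
        boxes_a = q.load_boxes(a)
        b = _write_labelme(tmp_path, [{"label": "n", "shape_type": "rectangle",
                                       "points": [[40, 60], [10, 20]]}])
        boxes_b = q.load_boxes(b, slide_id=boxes_a[0].slide_id)
        assert boxes_a == boxes_b
        assert (boxes_a[0].x_min, boxes_a[0].y_min) == (10, 20)
        assert (boxes_a[0].x_max, boxes_a[0].y_max) == (41, 61)  # inclusive corners

    def test_non_rectangles_skipped(self, tmp_path):
        path = _write_labelme(tmp_path, [
            {"label": "r", "shape_type": "rectangle", "points": [[0, 0], [5, 5]]},
            {"label": "p", "shape_type": "polygon", "points": [[0, 0], [5, 0], [3, 4]]},
        ])
        assert len(q.load_boxes(path)) == 1

    def test_empty_shapes(self, tmp_path):
        assert q.load_boxes(_write_labelme(tmp_path, [])) == []

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="bad.json"):
            q.load_boxes(path)


class TestSegmentNucleus:
    def test_clean_nucleus_mask_matches_ellipse_area(self):
        rng = sd.stream_rng(4, "geo")
        scene = sd.make_scene([3], rng)
        img, gt, _ = sd.render_smear(scene, seed=2)
        x0, y0, x1, y1 = gt["nuclei"][0]["box_xyxy"]
        box = q.NucleusBox("s", "b", x0, y0, x1 + 1, y1 + 1)
        mask, flags = q.segment_nucleus(img, box)
        assert flags == set()
        nuc = scene.nuclei[0]
        true_area = sd._nucleus_mask(nuc, scene.image_size).sum()
        assert abs(mask.sum() - true_area) / true_area < 0.15

    def test_uniform_background_is_no_nucleus(self, rng):
        img = np.clip(rng.normal(230, 8, (80, 80)), 0, 255).astype(np.uint8)
        mask, flags = q.segment_nucleus(img, q.NucleusBox("s", "b", 0, 0, 80, 80))
        assert flags == {"no_nucleus_found"}
        assert not mask.any()

    def test_two_nuclei_in_one_box_flagged(self):
        img = np.full((80, 140), 230, dtype=np.uint8)
        from skimage.draw import ellipse
        for cc in (35, 105):
            rr, c = ellipse(40, cc, 22, 24, shape=img.shape)
            img[rr, c] = 150
        _, flags = q.segment_nucleus(img, q.NucleusBox("s", "b", 0, 0, 140, 80))
        assert "overlapping_nuclei" in flags

    def test_mask_cut_by_box_edge_flagged(self):
        img = np.full((120, 120), 230, dtype=np.uint8)
        from skimage.draw import ellipse
        rr, cc = ellipse(60, 60, 30, 30, shape=img.shape)
        img[rr, cc] = 150
        # box clips the nucleus on two sides
        _, flags = q.segment_nucleus(img, q.NucleusBox("s", "b", 40, 40, 110, 110))
        assert "touches_box_edge" in flags

    def test_box_outside_image_rejected(self):
        img = np.full((50, 50), 230, dtype=np.uint8)
        with pytest.raises(ValueError, match="outside"):
            q.segment_nucleus(img, q.NucleusBox("s", "b", 10, 10, 60, 40))


class TestCountNors:
    @staticmethod
    def _nucleus_crop(dot_offsets, noise_rng=None):
        img = np.full((80, 80), 230.0)
        from skimage.draw import disk, ellipse
        rr, cc = ellipse(40, 40, 28, 28, shape=img.shape)
        img[rr, cc] = 150.0
        for dr, dc in dot_offsets:
            rr, cc = disk((40 + dr, 40 + dc), 3.0, shape=img.shape)
            img[rr, cc] = 30.0
        if noise_rng is not None:
            img += noise_rng.normal(0, 8, img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        mask, _ = q.segment_nucleus(img, q.NucleusBox("s", "b", 0, 0, 80, 80))
        return img, mask

    def test_five_disjoint_dots(self, rng):
        img, mask = self._nucleus_crop([(0, 0), (-15, 0), (15, 0), (0, -15), (0, 15)], rng)
        assert q.count_nors(img, mask) == 5

    def test_fused_pair_counts_once(self, rng):
        img, mask = self._nucleus_crop([(0, 0), (0, 4), (0, 18)], rng)
        assert q.count_nors(img, mask) == 2

    def test_no_dots_counts_zero(self, rng):
        img, mask = self._nucleus_crop([], rng)
        assert q.count_nors(img, mask) == 0

    def test_empty_mask_rejected(self):
        img = np.full((20, 20), 230, dtype=np.uint8)
        with pytest.raises(ValueError, match="mask"):
            q.count_nors(img, np.zeros((20, 20), dtype=bool))


class TestQuantifySlide:
    def test_counts_equal_ground_truth_on_clean_scene(self, rendered_slide):
        records = q.quantify_slide(rendered_slide["image"], rendered_slide["boxes"])
        truth = rendered_slide["truth"]
        assert len(records) == len(rendered_slide["boxes"])
        for r in records:
            assert r.status == "counted"
            assert r.nor_count == truth[r.box_id]

    def test_exclusion_conservation(self, rendered_slide):
        records = q.quantify_slide(rendered_slide["image"], rendered_slide["boxes"])
        counted = sum(r.status == "counted" for r in records)
        excluded = sum(r.status == "excluded" for r in records)
        assert counted + excluded == len(rendered_slide["boxes"])

    def test_overlap_scene_box_excluded(self):
        """A box spanning a close pair of nuclei is excluded as overlapping."""
        rng = sd.stream_rng(6, "geo")
        scene = sd.make_scene([2, 3], rng, n_overlapping_pairs=1)
        img, gt, _ = sd.render_smear(scene, seed=1)
        pair = [n for n in gt["nuclei"] if n["overlaps_other"]]
        assert len(pair) == 2
        x0 = min(n["box_xyxy"][0] for n in pair)
        y0 = min(n["box_xyxy"][1] for n in pair)
        x1 = max(n["box_xyxy"][2] for n in pair)
        y1 = max(n["box_xyxy"][3] for n in pair)
        singles = [
            q.NucleusBox("s", n["nucleus_id"], *(v + o for v, o in zip(n["box_xyxy"], (0, 0, 1, 1))))
            for n in gt["nuclei"]
            if not n["overlaps_other"]
        ]
        boxes = singles + [q.NucleusBox("s", "pair", x0, y0, x1 + 1, y1 + 1)]
        records = {r.box_id: r for r in q.quantify_slide(img, boxes)}
        assert records["pair"].status == "excluded"
        assert records["pair"].exclusion_reason == "overlapping_nuclei"
        assert all(records[b.box_id].status == "counted" for b in singles)

    def test_empty_box_list(self, rendered_slide):
        assert q.quantify_slide(rendered_slide["image"], []) == []

    def test_fused_dot_monotonicity(self):
        """Fusing two separate dots reduces the reported count by one."""
        rng = np.random.default_rng(0)
        img_sep, mask = TestCountNors._nucleus_crop([(0, -15), (0, 15)], rng)
        img_fused, mask_f = TestCountNors._nucleus_crop([(0, 0), (0, 4)], rng)
        assert q.count_nors(img_sep, mask) == 2
        assert q.count_nors(img_fused, mask_f) == 1

    def test_exclusion_summary_percentage(self):
        records = [q.NucleusRecord("a", "counted", nor_count=2),
                   q.NucleusRecord("b", "excluded", "zero_nors"),
                   q.NucleusRecord("c", "counted", nor_count=3)]
        n, pct = q.exclusion_summary(records)
        assert (n, pct) == (1, 33.33)

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            q.NucleusRecord("a", "counted")  # count missing
        with pytest.raises(ValueError):
            q.NucleusRecord("a", "counted", nor_count=14)
        with pytest.raises(ValueError):
            q.NucleusRecord("a", "excluded", "bad_reason")
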