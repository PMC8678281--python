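"""Chart rendering, degradation, cropping, boxes, VOC, split, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctgkit.charts import (
    BoundingBox,
    ChartDetectionError,
    ChartStyle,
    PageImage,
    augment,
    crop_chart_region,
    degrade,
    events_to_boxes,
    flip_horizontal,
    pixel_to_time,
    read_voc,
    render_pages,
    split_train_test,
    time_to_pixel,
    write_voc,
)
from ctgkit.signal import CTGFormatError, EventKind, EventLabel
from ctgkit.simulate import criterion_scenario, simulate_scenario

from conftest import make_flat_record


@pytest.fixture(scope="module")
def rendered():
    rec, truth = simulate_scenario(criterion_scenario("A", seed=1, noise_sd=1.0))
    pages = render_pages(rec, ChartStyle())
    return rec, truth, pages


class TestRender:
    def test_page_count_is_ceiling_of_duration(self):
        rec = make_flat_record(minutes=33)
        assert len(render_pages(rec, ChartStyle())) == 4

    def test_page_geometry(self):
        style = ChartStyle()
        assert style.page_width == 3 * 10 * 47 == 1410
        assert style.fhr_panel_height == round((240 - 30) / 30 * 47)

    def test_flat_trace_lands_on_mapped_row(self):
        rec = make_flat_record(fhr_bpm=140.0, minutes=10)
        page = render_pages(rec, ChartStyle())[0]
        _, y = time_to_pixel(300.0, 140.0, page)
        row = int(round(y)) - 1  # 1-based -> array index
        assert (page.pixels[row] == 0).mean() > 0.95
        assert (page.pixels[row - 4] == 0).mean() < 0.05

    def test_rendering_is_deterministic(self, rendered):
        rec, _, pages = rendered
        again = render_pages(rec, ChartStyle())
        for a, b in zip(pages, again):
            assert np.array_equal(a.pixels, b.pixels)

    def test_empty_record_renders_nothing(self):
        rec = make_flat_record(minutes=30)
        rec.fhr.values = rec.fhr.values[:0]
        rec.fhr.quality = rec.fhr.quality[:0]
        rec.uc.values = rec.uc.values[:0]
        assert render_pages(rec, ChartStyle()) == []


class TestDegrade:
    def test_level_zero_is_identity(self, rendered):
        _, _, pages = rendered
        out = degrade(pages[0], 0.0)
        assert np.array_equal(out.pixels, pages[0].pixels)

    def test_deterministic_given_seed(self, rendered):
        _, _, pages = rendered
        a = degrade(pages[0], 0.5, seed=3)
        b = degrade(pages[0], 0.5, seed=3)
        assert np.array_equal(a.pixels, b.pixels)

    def test_trace_survives_degradation(self):
        """Degraded against a degraded blank chart, the trace rows still
        darken at least 3× more than background rows."""
        rec = make_flat_record(fhr_bpm=140.0, minutes=10)
        page = render_pages(rec, ChartStyle())[0]
        # same grid, no trace: isolates the trace's contribution
        blank = make_flat_record(fhr_bpm=140.0, minutes=10)
        blank.fhr.quality[:] = False
        ref_page = render_pages(blank, ChartStyle())[0]
        out = degrade(page, 0.5, seed=1)
        ref = degrade(ref_page, 0.5, seed=1)
        diff = np.abs(out.pixels.astype(float) - ref.pixels.astype(float))
        _, y = time_to_pixel(300.0, 140.0, page)
        row = int(round(y)) - 1
        trace_dark = diff[row - 1:row + 2].mean()
        background = diff[row - 40:row - 20].mean()
        assert trace_dark >= 3 * max(background, 1.0)


class TestCrop:
    def test_header_and_footer_removed(self, rendered):
        _, _, pages = rendered
        style = pages[0].style
        c = crop_chart_region(pages[0])
        assert c.height == style.page_height - style.header_px - style.footer_px

    def test_idempotent_within_two_pixels(self, rendered):
        _, _, pages = rendered
        c1 = crop_chart_region(pages[0])
        c2 = crop_chart_region(c1)
        assert abs(c2.width - c1.width) <= 2
        assert abs(c2.height - c1.height) <= 2

    def test_blank_image_raises(self):
        page = PageImage(np.full((300, 400), 255, np.uint8), 0, 0.0, ChartStyle())
        with pytest.raises(ChartDetectionError):
            crop_chart_region(page)

    def test_mapping_survives_crop(self, rendered):
        rec, _, pages = rendered
        c = crop_chart_region(pages[1])
        t, v = 615.0, 137.0
        x, y = time_to_pixel(t, v, c)
        tt, vv = pixel_to_time(x, y, c)
        assert tt == pytest.approx(t, abs=1e-9)
        assert vv == pytest.approx(v, abs=1e-9)


class TestMapping:
    def test_page_start_maps_to_first_column(self, rendered):
        _, _, pages = rendered
        x, _ = time_to_pixel(pages[1].t0, 140.0, pages[1])
        assert x == pytest.approx(1.0)

    def test_page_spans_1410_columns_at_defaults(self, rendered):
        _, _, pages = rendered
        p = pages[0]
        x, _ = time_to_pixel(p.t0 + 600.0 - 1e-9, 140.0, p)
        assert 1410 <= x <= 1411
        assert p.width == 1410

    def test_out_of_page_time_rejected(self, rendered):
        _, _, pages = rendered
        with pytest.raises(ValueError):
            time_to_pixel(pages[0].t0 + 700.0, 140.0, pages[0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(t=st.floats(0, 599.9), v=st.floats(30, 240),
           channel=st.sampled_from(["fhr", "uc"]))
    def test_round_trip_within_half_pixel(self, t, v, channel):
        style = ChartStyle()
        page = PageImage(np.full((style.page_height, style.page_width), 255,
                                 np.uint8), 0, 0.0, style,
                         origin_x=1, fhr_top_y=style.header_px + 1,
                         uc_top_y=style.header_px + 400)
        if channel == "uc":
            v = v % 100
        x, y = time_to_pixel(t, v, page, channel)
        tt, vv = pixel_to_time(x, y, page, channel)
        assert abs(tt - t) <= 0.5 / style.px_per_s
        assert abs(vv - v) <= 0.5 * style.fhr_bpm_per_cm / style.px_per_cm


class TestBoxes:
    def test_event_inside_one_page(self, rendered):
        _, _, pages = rendered
        ev = EventLabel(EventKind.DECELERATION, 700.0, 800.0)
        boxes = events_to_boxes([ev], pages)
        assert len(boxes[1]) == 1
        assert all(len(boxes[i]) == 0 for i in boxes if i != 1)

    def test_straddling_event_split_partitions_padded_span(self, rendered):
        _, _, pages = rendered
        ev = EventLabel(EventKind.POINT_A, 560.0, 640.0)
        boxes = events_to_boxes([ev], pages, pad_s=30.0)
        assert len(boxes[0]) == 1 and len(boxes[1]) == 1
        b0, b1 = boxes[0][0], boxes[1][0]
        t0a, _ = pixel_to_time(b0.xmin, b0.ymin, pages[0])
        t0b, _ = pixel_to_time(b0.xmax, b0.ymin, pages[0])
        t1a, _ = pixel_to_time(b1.xmin, b1.ymin, pages[1])
        t1b, _ = pixel_to_time(b1.xmax, b1.ymin, pages[1])
        # spans partition [530, 670] up to pixel rounding
        assert t0a <= 530.0 + 0.5 and abs(t0b - 600.0) < 1.0
        assert abs(t1a - 600.0) < 1.0 and t1b >= 670.0 - 0.5
        assert b0.label == "point_a"

    def test_box_time_span_contains_event(self, rendered):
        rec, truth, pages = rendered
        boxes = events_to_boxes(truth.events, pages)
        for p in pages:
            for b in boxes[p.page_index]:
                ta, _ = pixel_to_time(b.xmin, b.ymin, p)
                tb, _ = pixel_to_time(b.xmax, b.ymin, p)
                matching = [e for e in truth.events
                            if (e.kind.value if hasattr(e.kind, "value") else e.kind) == b.label
                            and e.t_start < tb and e.t_end > ta]
                assert matching

    def test_empty_events_give_empty_pages(self, rendered):
        _, _, pages = rendered
        boxes = events_to_boxes([], pages)
        assert all(v == [] for v in boxes.values())


_box = st.builds(
    lambda x0, w, y0, h, label: BoundingBox(label, x0, y0, x0 + w, y0 + h),
    st.integers(1, 1200), st.integers(1, 200),
    st.integers(1, 400), st.integers(1, 100),
    st.sampled_from(["point_a", "deceleration", "overshoot"]),
)


class TestVoc:
    def test_single_box_file_structure(self, tmp_path):
        p = tmp_path / "a.xml"
        write_voc([BoundingBox("point_a", 10, 20, 110, 220)],
                  {"filename": "a.png", "width": 1410, "height": 531}, p)
        text = p.read_text()
        assert "<name>point_a</name>" in text
        assert "<width>1410</width>" in text

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(boxes=st.lists(_box, max_size=8))
    def test_round_trip(self, boxes, tmp_path_factory):
        p = tmp_path_factory.mktemp("voc") / "b.xml"
        write_voc(boxes, {"filename": "b.png", "width": 1410, "height": 531}, p)
        back, meta = read_voc(p)
        assert back == boxes
        assert meta["width"] == 1410

    def test_missing_bndbox_rejected(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<annotation><object><name>x</name></object></annotation>")
        with pytest.raises(CTGFormatError):
            read_voc(p)

    def test_malformed_xml_rejected(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<annotation><object>")
        with pytest.raises(CTGFormatError):
            read_voc(p)


class TestSplit:
    def test_paper_scale_arithmetic(self):
        sp = split_train_test(list(range(252)), seed=0)
        assert len(sp["train"]) == 202
        assert len(sp["test"]) + len(sp["validation"]) == 50
        assert len(sp["validation"]) == 25

    def test_small_split_disjoint_and_exhaustive(self):
        items = list(range(10))
        sp = split_train_test(items, seed=3)
        assert len(sp["train"]) == 8
        everything = sp["train"] + sp["test"] + sp["validation"]
        assert sorted(everything) == items

    def test_deterministic_by_seed(self):
        a = split_train_test(list(range(50)), seed=9)
        b = split_train_test(list(range(50)), seed=9)
        assert a == b

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_train_test([1, 2], seed=0)


class TestAugment:
    def test_quadruples_count_without_vertical_flip(self, rendered):
        _, truth, pages = rendered
        boxes = events_to_boxes(truth.events, pages)
        items = [(p.pixels, boxes[p.page_index]) for p in pages]
        out = augment(items)
        assert len(out) == 4 * len(items)
        for img, _, tag in out:
            # a vertical flip would reverse the row order; compare row-ink
            # profiles against the originals and their horizontal mirrors
            src = items[0][0]
            assert img.shape == src.shape
        tags = {tag for _, _, tag in out}
        assert tags == {"orig-reduced", "orig-sharpened",
                        "flip-reduced", "flip-sharpened"}

    def test_no_variant_is_vertically_flipped(self, rendered):
        _, _, pages = rendered
        src = pages[0].pixels
        profile = (255.0 - src).sum(axis=1)
        out = augment([(src, [])])
        for img, _, tag in out:
            p = (255.0 - img.astype(float)).sum(axis=1)
            straight = np.corrcoef(p, profile)[0, 1]
            flipped = np.corrcoef(p[::-1], profile)[0, 1]
            assert straight > flipped

    def test_flip_is_involution_on_boxes(self):
        img = np.zeros((100, 1410), np.uint8)
        b = BoundingBox("point_a", 100, 10, 200, 90)
        f_img, f_boxes = flip_horizontal(img, [b])
        assert (f_boxes[0].xmin, f_boxes[0].xmax) == (1211, 1311)
        _, back = flip_horizontal(f_img, f_boxes)
        assert back[0] == b

    def test_resolution_ops_leave_geometry(self, rendered):
        _, truth, pages = rendered
        boxes = events_to_boxes(truth.events, pages)
        items = [(pages[2].pixels, boxes[2])]
        for img, bxs, tag in augment(items):
            if tag.startswith("orig"):
                assert bxs == boxes[2]
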