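"""Synthetic colonoscopy corpus: determinism, similarity, annotations."""

import json

import numpy as np
import pytest
import yaml

from fpsiam.synthdata import (SyntheticSequence, SyntheticSequenceSpec,
                              _ALPHA_THRESHOLD, _render_polyp,
                              adjacent_frame_correlation, generate_sequence,
                              make_corpus, write_corpus)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Independent correlation routine (direct formula, float64)."""
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a, b = a - a.mean(), b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


class TestGenerateSequence:
    def test_polyp_prob_zero_means_no_polyps(self):
        spec = SyntheticSequenceSpec(n_frames=6, polyp_prob=0.0, seed=1)
        _, annos = generate_sequence(spec)
        assert all(not a.has_polyp and not a.boxes for a in annos)

    def test_deterministic_under_fixed_seed(self):
        spec = SyntheticSequenceSpec(n_frames=4, seed=9)
        f1, a1 = generate_sequence(spec)
        f2, a2 = generate_sequence(spec)
        assert np.array_equal(f1, f2)
        assert a1 == a2

    def test_adjacent_correlation_meets_target(self):
        spec = SyntheticSequenceSpec(n_frames=32, interframe_rho=0.9, seed=2)
        frames, _ = generate_sequence(spec)
        cors = [pearson(frames[i], frames[i + 1])
                for i in range(len(frames) - 1)]
        assert np.mean(cors) >= 0.85

    def test_frames_in_unit_range(self):
        frames, _ = generate_sequence(SyntheticSequenceSpec(n_frames=4, seed=3))
        assert frames.min() >= 0.0 and frames.max() <= 1.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSequenceSpec(polyp_prob=1.5)
        with pytest.raises(ValueError):
            SyntheticSequenceSpec(frame_size=16, polyp_axes_range=(6, 12))

    def test_boxes_bound_rendered_blob_exactly(self):
        """Every rendered blob pixel above threshold lies inside its box."""
        alpha, _ = _render_polyp(64, cx=30.3, cy=25.7, ax=9.0, ay=6.0,
                                 angle=0.7)
        mask = alpha > _ALPHA_THRESHOLD
        from fpsiam.synthdata import _tight_box
        x, y, w, h = _tight_box(alpha)
        ys, xs = np.nonzero(mask)
        assert xs.min() == x and ys.min() == y
        assert xs.max() == x + w - 1 and ys.max() == y + h - 1

    def test_polyp_sequences_have_boxes_inside_frame(self):
        spec = SyntheticSequenceSpec(n_frames=8, polyp_prob=1.0, seed=4)
        frames, annos = generate_sequence(spec)
        size = spec.frame_size
        for a in annos:
            assert a.has_polyp
            for (x, y, w, h) in a.boxes:
                assert 0 <= x and 0 <= y
                assert x + w <= size and y + h <= size


class TestCorpusSimilarityStructure:
    def test_within_exceeds_between_sequence_similarity(self):
        """Adjacent frames of one clip are more alike than frames from
        different clips — the property that breaks negative-pair methods."""
        within, between = [], []
        seqs = []
        for s in range(4):
            spec = SyntheticSequenceSpec(n_frames=8, seed=100 + s)
            frames, _ = generate_sequence(spec)
            seqs.append(frames)
            within += [pearson(frames[i], frames[i + 1]) for i in range(7)]
        for i in range(4):
            for j in range(i + 1, 4):
                between.append(pearson(seqs[i][0], seqs[j][0]))
        assert np.mean(within) > np.mean(between)


class TestWriteCorpus:
    @pytest.fixture
    def corpus_dir(self, tmp_path):
        sequences = []
        for s in range(2):
            spec = SyntheticSequenceSpec(n_frames=4, frame_size=32,
                                         polyp_prob=1.0,
                                         polyp_axes_range=(4, 8),
                                         seed=50 + s)
            frames, annos = generate_sequence(spec)
            sequences.append(SyntheticSequence(spec=spec, frames=frames,
                                               annotations=annos))
        out = write_corpus(sequences, tmp_path / "corpus")
        return out, sequences

    def test_counts(self, corpus_dir):
        out, _ = corpus_dir
        pngs = sorted(out.rglob("*.png"))
        assert len(pngs) == 8
        coco = json.loads((out / "annotations.json").read_text())
        assert len(coco["images"]) == 8

    def test_boxes_round_trip_exactly(self, corpus_dir):
        out, sequences = corpus_dir
        coco = json.loads((out / "annotations.json").read_text())
        by_image = {}
        for ann in coco["annotations"]:
            by_image.setdefault(ann["image_id"], []).append(tuple(ann["bbox"]))
        image_id = 0
        for seq in sequences:
            for a in seq.annotations:
                assert by_image.get(image_id, []) == \
                    [tuple(b) for b in a.boxes]
                image_id += 1

    def test_coco_schema_minimal(self, corpus_dir):
        out, _ = corpus_dir
        coco = json.loads((out / "annotations.json").read_text())
        assert set(coco) >= {"images", "annotations", "categories"}
        assert coco["categories"] == [{"id": 1, "name": "polyp"}]
        img_ids = [im["id"] for im in coco["images"]]
        ann_ids = [a["id"] for a in coco["annotations"]]
        assert len(set(img_ids)) == len(img_ids)
        assert len(set(ann_ids)) == len(ann_ids)
        for im in coco["images"]:
            assert {"id", "file_name", "width", "height"} <= set(im)
        for a in coco["annotations"]:
            assert {"id", "image_id", "category_id", "bbox"} <= set(a)
            assert a["image_id"] in set(img_ids)

    def test_manifest_records_specs(self, corpus_dir):
        out, sequences = corpus_dir
        manifest = yaml.safe_load((out / "manifest.yaml").read_text())
        assert len(manifest) == 2
        assert manifest[0]["seed"] == sequences[0].spec.seed

    def test_png_round_trip_preserves_frames(self, corpus_dir):
        from PIL import Image
        out, sequences = corpus_dir
        arr = np.asarray(Image.open(out / "seq_000" / "frame_0000.png"))
        orig = (np.clip(sequences[0].frames[0], 0, 1) * 255 + 0.5).astype(np.uint8)
        assert np.array_equal(arr, orig.transpose(1, 2, 0))


def test_make_corpus_shape():
    frames = make_corpus(40, frame_size=32, seq_len=16, seed=0)
    assert frames.shape == (40, 3, 32, 32)
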