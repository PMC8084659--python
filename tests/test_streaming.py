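"""Micro-batch engine: exactly-once delivery, equivalence, progress report."""

import numpy as np
import pytest

from ecgstream.classify import predict, save_model, train
from ecgstream.errors import SpecificationError
from ecgstream.features import extract_features, features_matrix
from ecgstream.io import open_stream
from ecgstream.preprocess import bandpass_fir, detect_r_peaks, segment_beats
from ecgstream.streaming import (
    BatchResult,
    Checkpoint,
    CsvDirSink,
    QueryConfig,
    SqliteSink,
    progress_report,
    run_query,
    sink_write,
)
from ecgstream.synthetic import generate_dataset, rhythm_for, template_for
from ecgstream.workflows import synthetic_benchmark


class SimulatedCrash(RuntimeError):
    pass


@pytest.fixture(scope="module")
def model(tmp_path_factory):
    train_ds, _ = synthetic_benchmark(seed=5, duration_s=40.0)
    mdl = train(train_ds, "random_forest", seed=5)
    path = tmp_path_factory.mktemp("model") / "model.bin"
    save_model(mdl, path)
    return mdl, path


def _make_source(tmp_path, seconds_per_class=15.0, seed=30):
    specs = [
        (
            rhythm_for(cls, seconds_per_class, seed + i, noise_sd=0.05),
            template_for(cls),
        )
        for i, cls in enumerate(("NORMAL", "RBBB", "AF"))
    ]
    src = tmp_path / "src"
    generate_dataset(specs, src)
    return src


def _config(tmp_path, src, model_path, **kw):
    return QueryConfig(
        source_dir=str(src),
        sink_uri=str(tmp_path / "sink"),
        checkpoint_path=str(tmp_path / "checkpoint.json"),
        model_path=str(model_path),
        **kw,
    )


def _batch_mode_predictions(src, mdl):
    """Single-batch oracle: the whole concatenated record at once."""
    packets = list(open_stream(src))
    signal = np.concatenate([p.samples for p in packets])
    filtered = bandpass_fir(signal)
    seg = segment_beats(filtered, detect_r_peaks(filtered))
    labels, _ = predict(
        mdl, features_matrix([extract_features(b) for b in seg.beats])
    )
    return sorted(zip((b.r_index for b in seg.beats), labels))


class TestRunQuery:
    def test_three_packet_stream_gives_three_batches(self, tmp_path, model):
        mdl, model_path = model
        src = _make_source(tmp_path, seconds_per_class=5.0)
        results = run_query(_config(tmp_path, src, model_path))
        assert len(results) == 3
        assert [r.packet_index for r in results] == [0, 1, 2]
        assert all(r.n_beats == len(r.labels) for r in results)

    def test_batch_stream_equivalence_with_carry_over(self, tmp_path, model):
        mdl, model_path = model
        src = _make_source(tmp_path)
        results = run_query(_config(tmp_path, src, model_path))
        streamed = sorted(
            (r, l)
            for res in results
            for r, l in zip(res.r_indices, res.labels)
        )
        assert streamed == _batch_mode_predictions(src, mdl)

    def test_empty_source_exits_cleanly(self, tmp_path, model):
        _, model_path = model
        (tmp_path / "src").mkdir()
        results = run_query(_config(tmp_path, tmp_path / "src", model_path))
        assert results == []

    def test_restart_after_commit_skips_done_batches(self, tmp_path, model):
        mdl, model_path = model
        src = _make_source(tmp_path)
        cfg = _config(tmp_path, src, model_path)

        def crash_after_batch_1(stage, k):
            if stage == "checkpoint" and k == 1:
                raise SimulatedCrash

        with pytest.raises(SimulatedCrash):
            run_query(cfg, failpoint=crash_after_batch_1)
        resumed = run_query(cfg)
        assert min(r.packet_index for r in resumed) == 2
        # the union of both runs still equals the batch-mode oracle
        sink = CsvDirSink(cfg.sink_uri)
        rows = sink.read_rows()
        assert sorted(zip(rows.r_index, rows.label)) == _batch_mode_predictions(
            src, mdl
        )

    def test_crash_between_sink_and_checkpoint_not_double_committed(
        self, tmp_path, model
    ):
        mdl, model_path = model
        src = _make_source(tmp_path, seconds_per_class=10.0)
        cfg = _config(tmp_path, src, model_path)

        def crash(stage, k):
            if stage == "sink" and k == 2:
                raise SimulatedCrash

        with pytest.raises(SimulatedCrash):
            run_query(cfg, failpoint=crash)
        run_query(cfg)
        rows = CsvDirSink(cfg.sink_uri).read_rows()
        assert rows.r_index.is_unique
        assert sorted(zip(rows.r_index, rows.label)) == _batch_mode_predictions(
            src, mdl
        )

    def test_no_carry_over_drops_packet_boundary_beats(self, tmp_path, model):
        mdl, model_path = model
        src = _make_source(tmp_path)
        results = run_query(
            _config(tmp_path, src, model_path, carry_over=False)
        )
        streamed = [r for res in results for r in res.r_indices]
        batch = [r for r, _ in _batch_mode_predictions(src, mdl)]
        assert set(streamed) <= set(batch)
        assert len(streamed) <= len(batch)

    def test_quarantined_packet_keeps_stream_alive(self, tmp_path, model):
        _, model_path = model
        src = _make_source(tmp_path, seconds_per_class=5.0)
        (src / "packet_00001.csv").write_text(
            "# fs=360 start_sample=1800 record=x\nvalue_mv\ngarbage\n"
        )
        with pytest.warns(UserWarning):
            results = run_query(_config(tmp_path, src, model_path))
        assert len(results) == 3
        assert results[1].quarantined and results[1].n_beats == 0


class TestSinks:
    ROWS = [
        {"packet_index": 0, "record": "r", "r_index": 500, "label": "AF", "ts": "t"}
    ]

    @pytest.mark.parametrize("sink_cls", [CsvDirSink, SqliteSink])
    def test_idempotent_rewrite(self, tmp_path, sink_cls):
        sink = sink_cls(tmp_path / "s")
        assert sink_write(sink, 0, self.ROWS).startswith("ok")
        assert sink_write(sink, 0, self.ROWS).startswith("dup")
        assert len(sink.read_rows()) == 1

    @pytest.mark.parametrize("sink_cls", [CsvDirSink, SqliteSink])
    def test_rows_appended_in_packet_order(self, tmp_path, sink_cls):
        sink = sink_cls(tmp_path / "s")
        rows1 = [dict(self.ROWS[0], packet_index=1, r_index=900)]
        sink_write(sink, 1, rows1)
        sink_write(sink, 0, self.ROWS)
        df = sink.read_rows()
        assert list(df.sort_values("packet_index").r_index) == [500, 900]
        assert sink.committed() == {0, 1}

    @pytest.mark.parametrize("sink_cls", [CsvDirSink, SqliteSink])
    def test_read_back_reconstructs_labels(self, tmp_path, sink_cls):
        sink = sink_cls(tmp_path / "s")
        sink_write(sink, 0, self.ROWS)
        df = sink.read_rows()
        assert list(df.label) == ["AF"] and list(df.r_index) == [500]


class TestCheckpoint:
    def test_starts_at_minus_one_and_advances(self, tmp_path):
        ckpt = Checkpoint(tmp_path / "c.json")
        assert ckpt.last_committed() == -1
        ckpt.commit(0)
        ckpt.commit(3)
        assert ckpt.last_committed() == 3

    def test_monotonicity_enforced(self, tmp_path):
        ckpt = Checkpoint(tmp_path / "c.json")
        ckpt.commit(5)
        with pytest.raises(SpecificationError):
            ckpt.commit(2)


class TestProgressReport:
    def test_one_row_per_batch_with_sane_timings(self, tmp_path, model):
        _, model_path = model
        src = _make_source(tmp_path)
        results = run_query(_config(tmp_path, src, model_path))
        df = progress_report(results, tmp_path / "progress.csv")
        assert len(df) == len(results)
        for col in ("read_ms", "compute_ms", "sink_ms", "total_ms"):
            assert (df[col] >= 0).all()
        comp = df[["read_ms", "compute_ms", "sink_ms"]].max(axis=1)
        assert (df.total_ms >= comp - 1e-6).all()
        assert df.attrs["mean_total_ms"] == pytest.approx(df.total_ms.mean())
        assert (tmp_path / "progress.csv").exists()

    def test_empty_results_rejected(self):
        with pytest.raises(SpecificationError):
            progress_report([])
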