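import math

import numpy as np
import pandas as pd
import pytest

from osn_stream.concentration import (
    ascending_pair_diffs,
    build_series,
    concentration_summary,
    mouse_mean_amplitude,
    normalize_to_top,
)
from osn_stream.model import SchedulePanel, StimulusSchedule

LADDER = (0.005, 0.01, 0.05, 0.10)


def _panel(odorant="eb"):
    entries = {}
    for c in LADDER:
        label = f"{odorant}_{c:g}"
        entries[label] = StimulusSchedule(label, odorant, c, False, 4.0, 1.0, 20.0, 15.0)
    return SchedulePanel(entries)


def _metrics_row(roi, conc, dff, responder, mouse="m1", latency=0.5, ttp=1.0, odorant="eb"):
    return {
        "roi_id": roi, "mouse_id": mouse, "stimulus_label": f"{odorant}_{conc:g}",
        "baseline_mean": 100.0, "baseline_sd": 1.0, "delta_f": dff,
        "dff_pct": dff if responder else 0.0, "is_responder": responder,
        "latency_s": latency if responder else math.nan,
        "time_to_peak_s": ttp if responder else math.nan,
        "integral_pct_s": dff * 2 if responder else math.nan,
        "dff_blanksub_pct": dff if responder else 0.0,
    }


def _metrics(rows):
    return pd.DataFrame(rows)


def test_mean_includes_zeros_for_nonresponding_included_glomeruli():
    rows = []
    for c in LADDER:
        rows.append(_metrics_row("g1", c, 10.0, True))
        rows.append(_metrics_row("g2", c, 8.0 if c == 0.10 else 0.0, c == 0.10))
    series = build_series(_metrics(rows), _panel())
    out = mouse_mean_amplitude(series).set_index("concentration")
    # g2 responds only at 10%: contributes zeros at the lower rungs
    assert out.loc[0.005, "mean_dff"] == pytest.approx(5.0)
    assert out.loc[0.10, "mean_dff"] == pytest.approx(9.0)
    assert (out["n_glomeruli"] == 2).all()


def test_inclusion_rule_drops_fully_unresponsive_glomeruli():
    rows = [_metrics_row("g1", c, 0.0, False) for c in LADDER]
    rows += [_metrics_row("g2", c, 10.0, True) for c in LADDER]
    series = build_series(_metrics(rows), _panel())
    assert {s.roi_id for s in series} == {"g2"}


def test_normalize_to_top_ladder():
    rows = [
        _metrics_row("g1", c, d, True)
        for c, d in zip(LADDER, (2.0, 4.0, 8.0, 10.0))
    ]
    series = normalize_to_top(build_series(_metrics(rows), _panel()))
    amp = series[0].amplitude
    assert [amp[c] for c in LADDER] == pytest.approx([0.2, 0.4, 0.8, 1.0])


def test_normalize_nonresponder_at_mid_rung_is_zero():
    rows = [
        _metrics_row("g1", c, 0.0 if c == 0.05 else 10.0, c != 0.05)
        for c in LADDER
    ]
    series = normalize_to_top(build_series(_metrics(rows), _panel()))
    assert series[0].amplitude[0.05] == 0.0


def test_normalize_excludes_glomerulus_without_top_response():
    rows = [
        _metrics_row("g1", c, 10.0 if c == 0.005 else 0.0, c == 0.005)
        for c in LADDER
    ]
    assert normalize_to_top(build_series(_metrics(rows), _panel())) == []


def test_mean_normalized_invariant_to_per_glomerulus_gain():
    rng = np.random.default_rng(0)
    base = {0.005: 2.0, 0.01: 4.0, 0.05: 8.0, 0.10: 10.0}
    rows_a, rows_b = [], []
    for g in range(6):
        gain = rng.uniform(0.5, 4.0)
        for c in LADDER:
            rows_a.append(_metrics_row(f"g{g}", c, base[c], True))
            rows_b.append(_metrics_row(f"g{g}", c, base[c] * gain, True))
    panel = _panel()
    out_a = mouse_mean_amplitude(normalize_to_top(build_series(_metrics(rows_a), panel)))
    out_b = mouse_mean_amplitude(normalize_to_top(build_series(_metrics(rows_b), panel)))
    np.testing.assert_allclose(out_a["mean_dff"], out_b["mean_dff"], rtol=1e-12)


class TestAscendingPairDiffs:
    def test_latency_shortening_is_negative(self):
        rows = [
            _metrics_row("g1", 0.005, 10.0, True, latency=0.8),
            _metrics_row("g1", 0.01, 12.0, True, latency=0.5),
            _metrics_row("g1", 0.05, 13.0, False),
            _metrics_row("g1", 0.10, 14.0, True, latency=0.3),
        ]
        out = ascending_pair_diffs(build_series(_metrics(rows), _panel()), "latency")
        out = out.set_index("pair")
        assert out.loc["0.005-0.01", "mean_diff"] == pytest.approx(-0.3)
        # non-responder at 5% removes both adjacent pairs
        assert set(out.index) == {"0.005-0.01"}

    def test_single_concentration_responder_contributes_no_pair(self):
        rows = [
            _metrics_row("g1", c, 10.0 if c == 0.01 else 0.0, c == 0.01)
            for c in LADDER
        ]
        out = ascending_pair_diffs(build_series(_metrics(rows), _panel()), "dff")
        assert len(out) == 0

    def test_monotone_metric_gives_single_signed_diffs(self):
        rows = [
            _metrics_row("g1", c, d, True)
            for c, d in zip(LADDER, (1.0, 3.0, 7.0, 9.0))
        ]
        out = ascending_pair_diffs(build_series(_metrics(rows), _panel()), "dff")
        assert (out["mean_diff"] > 0).all()
        assert len(out) == 3

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            ascending_pair_diffs([], "amplitude")


def test_concentration_summary_combines_raw_and_normalized():
    rows = [
        _metrics_row("g1", c, d, True)
        for c, d in zip(LADDER, (2.0, 4.0, 8.0, 10.0))
    ]
    out = concentration_summary(_metrics(rows), _panel()).set_index("concentration")
    assert out.loc[0.10, "mean_dff"] == pytest.approx(10.0)
    assert out.loc[0.10, "mean_norm_dff"] == pytest.approx(1.0)
    assert out.loc[0.005, "mean_norm_dff"] == pytest.approx(0.2)
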