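"""End-to-end analysis pipeline.

Chains the preprocessing, event-detection, parameter-extraction,
adaptation and statistics stages: a :class:`TrialRecording` goes in, a
per-step parameter table comes out; a cohort of subjects becomes an
outcome table ready for the mixed-effects group comparison.

The adaptation metrics can be computed either from extracted step tables
(the full pipeline) or directly from generator step truth (useful for
large statistical simulations where rendering continuous signals for
every subject would add nothing but runtime).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import events as ev
from .adaptation import (aftereffect_magnitude, build_symmetry_series,
                         percent_change, plateau_magnitude, steps_to_plateau)
from .parameters import PARAMETERS, extract_all
from .preprocessing import (Signal, compute_baseline_stats, fill_gaps,
                            lowpass_filter)

__all__ = [
    "process_trial",
    "trial_step_table",
    "adaptation_outcomes",
    "cohort_outcome_table",
]


def process_trial(trial, filter_cutoff_hz: float | None = 10.0,
                  filter_order: int = 4, max_gap_ms: float = 100.0,
                  detect_kwargs: dict | None = None):
    """Run preprocessing + event detection + extraction for one trial.

    Returns ``(step_df, gait_events)``.  ``filter_cutoff_hz=None`` skips
    filtering (useful on noise-free synthetic data).  Marker gaps are
    spline-filled; gaps too long to fill become exclusion intervals that
    invalidate the overlapping steps.
    """
    detect_kwargs = detect_kwargs or {}
    fs = trial.fs_marker
    markers = {}
    exclusions = []
    for name, axes in trial.markers.items():
        markers[name] = {}
        for axis, vals in axes.items():
            sig = Signal(np.asarray(vals, dtype=float), fs,
                         trial.marker_mask[name].copy())
            sig, excl = fill_gaps(sig, max_gap_ms=max_gap_ms)
            exclusions.extend(excl)
            if filter_cutoff_hz is not None:
                sig = lowpass_filter(sig, cutoff_hz=filter_cutoff_hz, order=filter_order)
            markers[name][axis] = sig.values
    hs_l = ev.detect_heel_strikes(Signal(markers["heel_l"]["ap"], fs), exclusions=exclusions, **detect_kwargs)
    hs_r = ev.detect_heel_strikes(Signal(markers["heel_r"]["ap"], fs), exclusions=exclusions, **detect_kwargs)
    po_l = ev.detect_pushoffs(Signal(markers["toe_l"]["ap"], fs), exclusions=exclusions, **detect_kwargs)
    po_r = ev.detect_pushoffs(Signal(markers["toe_r"]["ap"], fs), exclusions=exclusions, **detect_kwargs)
    gait_events = ev.assemble_events(hs_l, hs_r, po_l, po_r, exclusions=exclusions)
    step_df = extract_all(trial, gait_events, markers=markers)
    step_df.insert(0, "condition", trial.condition)
    step_df.insert(0, "group", trial.group)
    step_df.insert(0, "subject", trial.subject)
    return step_df, gait_events


def trial_step_table(subject, **kwargs) -> pd.DataFrame:
    """Step tables for all recorded conditions of one cohort subject."""
    frames = []
    for cond in subject.recordings:
        step_df, _ = process_trial(subject.recordings[cond], **kwargs)
        frames.append(step_df)
    return pd.concat(frames, ignore_index=True)


def adaptation_outcomes(step_table: pd.DataFrame,
                        plateau_steps_as_percent: bool = False) -> pd.DataFrame:
    """Per-parameter adaptation metrics for one subject.

    ``step_table`` holds all conditions of one subject (truth or
    extracted).  Baseline statistics come from the baseline-slow steps;
    magnitudes are converted to percent change from the baseline-slow
    reference.  Steps to plateau are reported as raw counts by default,
    or as percent of the split-series length.
    """
    baseline = compute_baseline_stats(
        step_table[step_table["condition"] == "baseline_slow"], PARAMETERS)
    rows = []
    for param in PARAMETERS:
        split_sym = build_symmetry_series(step_table, baseline, param, "split")
        after_sym = build_symmetry_series(step_table, baseline, param, "after")
        res = steps_to_plateau(split_sym)
        mag = plateau_magnitude(split_sym, res)
        after_mag = aftereffect_magnitude(after_sym)
        stp = res.steps_to_plateau
        rows.append({
            "parameter": param,
            "steps_to_plateau": (100.0 * stp / len(split_sym)
                                 if plateau_steps_as_percent else stp),
            "plateau_magnitude": percent_change(mag, baseline, param),
            "aftereffect": percent_change(after_mag, baseline, param),
            "converged": res.converged,
        })
    return pd.DataFrame(rows)


def cohort_outcome_table(subjects, response: str = "aftereffect",
                         source: str = "truth", **kwargs) -> pd.DataFrame:
    """Build the mixed-model outcome table for a cohort.

    ``response`` is one of ``steps_to_plateau`` / ``plateau_magnitude`` /
    ``aftereffect``; ``source`` selects generator truth tables
    (``"truth"``) or the full signal pipeline (``"pipeline"``, requires
    recordings).  Returns rows (subject, group, parameter, value).
    """
    rows = []
    for subj in subjects:
        if source == "truth":
            table = subj.truth.table.assign(valid=True)
        elif source == "pipeline":
            table = trial_step_table(subj, **kwargs)
        else:
            raise ValueError(f"unknown source {source!r}")
        out = adaptation_outcomes(table)
        for _, r in out.iterrows():
            rows.append({"subject": subj.subject, "group": subj.group,
                         "parameter": r["parameter"], "value": r[response]})
    return pd.DataFrame(rows)
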