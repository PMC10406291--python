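"""Per-run figures, consolidated QC decisions, and the two report documents.

Mirrors the split used in practice: one report for the image side (motion
traces with censoring, temporal-summary montages, metadata consistency)
and one for the behavioral side (trial/response raster with margin
statistics), plus a machine-readable JSON array of per-run decisions.
Decision logic is a pure function of the per-criterion results, so the
stored ``excluded`` flag can always be re-derived from the record.
"""
from __future__ import annotations

import base64
import html
import io
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from string import Template
from typing import Any, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .image_qc import montage
from .types import (
    BehaviorResult,
    CensorResult,
    EventsTable,
    MetadataMismatch,
    MotionRecord,
    QCDecision,
    RunImage,
    TrialCensorOverlap,
    VolumeSummaries,
)

QC_SCHEMA_VERSION = "1.0"

TRIAL_TYPE_COLORS = ("tab:green", "tab:olive", "tab:purple", "tab:brown")
RESPONSE_KEY_COLORS = ("tab:blue", "tab:red", "tab:orange", "tab:cyan")


@dataclass
class RunRecord:
    """Everything computed for one run, ready for reporting."""

    run_id: str
    events: EventsTable | None = None
    motion: MotionRecord | None = None
    image: RunImage | None = None
    censor: CensorResult | None = None
    behavior: BehaviorResult | None = None
    summaries: VolumeSummaries | None = None
    overlap: TrialCensorOverlap | None = None
    notes: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)


def decide(record: RunRecord,
           metadata_deviant: bool = False,
           override: tuple[str, str] | None = None) -> QCDecision:
    """Combine criterion results into one :class:`QCDecision`.

    ``override`` is (state, note) for criterion D — the recorded human
    judgment the qualitative criterion requires.  Without an override,
    criterion D is ``needs_review`` when the run's metadata deviates from
    the dataset majority, else ``pass``.
    """
    a = "fail" if record.censor is not None and record.censor.exclude_run else "pass"
    b = "fail" if record.behavior is not None and record.behavior.flags.criterion_b_exclude \
        else "pass"
    c = "fail" if record.behavior is not None and record.behavior.flags.criterion_c_exclude \
        else "pass"
    if override is not None:
        d_state, note = override
    else:
        d_state, note = ("needs_review" if metadata_deviant else "pass"), None
    return QCDecision(run_id=record.run_id, criterion_a=a, criterion_b=b,
                      criterion_c=c, criterion_d=d_state, override_note=note)


def decide_all(records: Sequence[RunRecord],
               mismatches: Sequence[MetadataMismatch] = (),
               overrides: dict[str, tuple[str, str]] | None = None) -> list[QCDecision]:
    """Decisions for a whole dataset, marking metadata deviants for review."""
    overrides = overrides or {}
    deviant_ids = {rid for m in mismatches for rid, _ in m.deviants}
    return [
        decide(r, metadata_deviant=r.run_id in deviant_ids,
               override=overrides.get(r.run_id))
        for r in records
    ]


# ---------------------------------------------------------------- figures

def _fig_to_png_bytes(fig: plt.Figure) -> bytes:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    plt.close(fig)
    return buf.getvalue()


def motion_figure(motion: MotionRecord, censor: CensorResult,
                  events: EventsTable | None = None,
                  out_path: str | None = None, tr_s: float = 2.0) -> bytes:
    """Realignment-parameter and FD line plots for one run.

    Shows the six parameter traces, the FD trace with the censoring
    threshold line, trial-onset marks, markers at censored frames, and the
    censored count/fraction printed on the plot (for quick comparison to
    the run-exclusion fraction).
    """
    if motion.run_id != censor.run_id:
        raise ValidationError(
            f"run mismatch: motion {motion.run_id!r} vs censor {censor.run_id!r}"
        )
    frames = np.arange(motion.n_frames)
    fig, axes = plt.subplots(3, 1, figsize=(9, 6), sharex=True,
                             gridspec_kw={"height_ratios": [2, 2, 1.5]})
    for i, name in enumerate(("x", "y", "z")):
        axes[0].plot(frames, motion.trans[:, i], lw=0.8, label=f"trans_{name}")
    axes[0].set_ylabel("mm")
    axes[0].legend(loc="upper right", fontsize=7, ncol=3)
    for i, name in enumerate(("x", "y", "z")):
        axes[1].plot(frames, motion.rot[:, i], lw=0.8, label=f"rot_{name}")
    axes[1].set_ylabel("rad")
    axes[1].legend(loc="upper right", fontsize=7, ncol=3)

    fd = motion.fd if motion.fd is not None else np.zeros(motion.n_frames)
    axes[2].plot(frames, fd, color="black", lw=0.9, label="FD")
    axes[2].axhline(censor.threshold_mm, color="tab:red", ls="--", lw=0.8,
                    label=f"threshold {censor.threshold_mm} mm")
    idx = censor.censored_frame_indices
    if idx:
        axes[2].plot(idx, fd[idx], "rv", ms=5, label="censored")
    axes[2].set_ylabel("FD (mm)")
    axes[2].set_xlabel("frame")
    annotation = f"censored: {censor.n_censored} ({censor.frac_censored:.1%})"
    axes[2].text(0.01, 0.95, annotation, transform=axes[2].transAxes,
                 va="top", fontsize=9)

    if events is not None:
        if events.run_id != motion.run_id:
            raise ValidationError(
                f"run mismatch: events {events.run_id!r} vs motion {motion.run_id!r}"
            )
        # onsets are seconds; TR converts them to the frame axis
        for ax in axes:
            for onset in events.trials["onset"]:
                ax.axvline(onset / tr_s, color="gray", lw=0.3, alpha=0.4, zorder=0)
    fig.suptitle(f"{motion.run_id} — motion and censoring")

    png = _fig_to_png_bytes(fig)
    if out_path:
        with open(out_path, "wb") as fh:
            fh.write(png)
    return png


def behavior_figure(events_list: Sequence[EventsTable],
                    behavior_list: Sequence[BehaviorResult],
                    out_path: str | None = None) -> bytes:
    """One-row-per-run raster of trials, responses, and accuracy.

    Trial onsets are colored by trial type; responses are drawn at
    onset + response time colored by key, with black ticks on correct
    responses.  The right margin prints per-key counts, the total, and the
    proportion correct among responded trials.  Vertical gridlines mark
    1-minute intervals.
    """
    if not events_list or len(events_list) != len(behavior_list):
        raise ValidationError("events and behavior lists must be non-empty and aligned")
    for ev, bh in zip(events_list, behavior_list):
        if ev.run_id != bh.run_id:
            raise ValidationError(f"run mismatch: {ev.run_id!r} vs {bh.run_id!r}")

    types = sorted({t for ev in events_list for t in ev.trials["trial_type"] if t})
    keys = sorted({k for bh in behavior_list for k in bh.n_responses_by_key})
    type_color = {t: TRIAL_TYPE_COLORS[i % len(TRIAL_TYPE_COLORS)]
                  for i, t in enumerate(types)}
    key_color = {k: RESPONSE_KEY_COLORS[i % len(RESPONSE_KEY_COLORS)]
                 for i, k in enumerate(keys)}

    t_max = max(float(ev.trials["onset"].max()) for ev in events_list) + 10
    fig, ax = plt.subplots(figsize=(11, 0.55 * len(events_list) + 1.5))
    for minute in np.arange(0, t_max, 60):
        ax.axvline(minute, color="lightgray", lw=0.6, zorder=0)

    for row, (ev, bh) in enumerate(zip(events_list, behavior_list)):
        y = len(events_list) - 1 - row
        for _, trial in ev.trials.iterrows():
            ax.plot([trial["onset"]] * 2, [y - 0.35, y + 0.05], lw=1.2,
                    color=type_color.get(trial["trial_type"], "gray"))
            if trial["response"] is not None and not (
                isinstance(trial["response"], float) and np.isnan(trial["response"])
            ):
                t_resp = trial["onset"] + trial["response_time"]
                ax.plot([t_resp] * 2, [y - 0.05, y + 0.35], lw=1.2,
                        color=key_color.get(trial["response"], "black"))
                if trial["correct"] is True:
                    ax.plot(t_resp, y + 0.4, marker="|", color="black", ms=5)
        counts = " ".join(f"{k}:{bh.n_responses_by_key.get(k, 0)}" for k in keys)
        acc = "n/a" if bh.accuracy_responded is None else f"{bh.accuracy_responded:.2f}"
        ax.text(t_max + 5, y, f"{counts}  tot:{bh.n_responses_total}  acc:{acc}",
                va="center", fontsize=7)

    ax.set_yticks(range(len(events_list)))
    ax.set_yticklabels([ev.run_id for ev in reversed(events_list)], fontsize=8)
    ax.set_xlim(-5, t_max * 1.28)
    ax.set_xlabel("time (s)")
    ax.set_title("Task presentation and responses")
    handles = [plt.Line2D([], [], color=c, label=t) for t, c in type_color.items()]
    handles += [plt.Line2D([], [], color=c, label=k) for k, c in key_color.items()]
    ax.legend(handles=handles, loc="upper left", fontsize=7, ncol=len(handles))

    png = _fig_to_png_bytes(fig)
    if out_path:
        with open(out_path, "wb") as fh:
            fh.write(png)
    return png


def summary_image_figure(summaries: VolumeSummaries, n_slices: int = 6,
                         out_path: str | None = None) -> bytes:
    """Axial montages of the temporal mean, sd, and tSNR volumes of one run."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for ax, (vol, label) in zip(
        axes,
        [(summaries.mean_vol, "mean"), (summaries.sd_vol, "sd"),
         (summaries.tsnr_vol, "tSNR")],
    ):
        n = min(n_slices, vol.shape[2])
        tiled, _ = montage(vol, n_slices=n, axis="axial")
        ax.imshow(tiled, cmap="gray", vmin=0, vmax=1, interpolation="nearest")
        ax.set_title(f"{summaries.run_id} {label}", fontsize=9)
        ax.axis("off")
    fig.text(0.01, 0.02, "neurological orientation (left on left)", fontsize=6)
    png = _fig_to_png_bytes(fig)
    if out_path:
        with open(out_path, "wb") as fh:
            fh.write(png)
    return png


# ---------------------------------------------------------------- reports

_PAGE = Template("""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>$title</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 70em; }
table { border-collapse: collapse; } td, th { border: 1px solid #999; padding: 4px 8px; }
.fail { background: #fdd; } .review { background: #ffd; }
img { max-width: 100%; }
</style></head>
<body>
<h1>$title</h1>
$timestamp
$body
</body></html>
""")


def _img_tag(png: bytes) -> str:
    return f'<img src="data:image/png;base64,{base64.b64encode(png).decode()}">'


def _decision_table(decisions: Sequence[QCDecision]) -> str:
    rows = []
    for d in decisions:
        cells = []
        for crit in (d.criterion_a, d.criterion_b, d.criterion_c, d.criterion_d):
            css = "fail" if crit in ("fail", "fail_by_override") else (
                "review" if crit == "needs_review" else "")
            cells.append(f'<td class="{css}">{html.escape(crit)}</td>')
        note = html.escape(d.override_note or "")
        rows.append(
            f"<tr><td>{html.escape(d.run_id)}</td>{''.join(cells)}"
            f"<td>{'excluded' if d.excluded else 'included'}</td><td>{note}</td></tr>"
        )
    return (
        "<table><tr><th>run</th><th>A motion</th><th>B presentation</th>"
        "<th>C performance</th><th>D images</th><th>decision</th><th>note</th></tr>"
        + "".join(rows) + "</table>"
    )


def build_reports(records: Sequence[RunRecord], decisions: Sequence[QCDecision],
                  out_dir: str, timestamp: bool = False,
                  mismatches: Sequence[MetadataMismatch] = ()) -> dict[str, str]:
    """Write the two HTML reports plus the machine-readable decision JSON.

    Returns the paths written.  The JSON is deterministic (sorted keys, no
    timestamps) so a rerun on identical inputs is byte-identical; the HTML
    embeds a timestamp only when ``timestamp`` is set.
    """
    decided = {d.run_id for d in decisions}
    for r in records:
        if r.run_id not in decided:
            raise ValidationError(f"no decision provided for run {r.run_id!r}")
    os.makedirs(out_dir, exist_ok=True)
    stamp = (
        f"<p>generated {datetime.now(timezone.utc).isoformat(timespec='seconds')}</p>"
        if timestamp else ""
    )

    # --- image/motion report
    parts = ["<h2>Decisions</h2>", _decision_table(decisions),
             "<h2>Motion and censoring (criterion A)</h2>"]
    for r in records:
        if r.motion is not None and r.censor is not None:
            parts.append(_img_tag(motion_figure(r.motion, r.censor, r.events)))
        if r.overlap is not None:
            parts.append(
                f"<p>{html.escape(r.run_id)}: {r.overlap.n_censored_in_trials} censored "
                f"frames inside trials, {r.overlap.n_censored_outside_trials} outside; "
                f"{r.overlap.n_trials_affected} trials affected.</p>"
            )
    parts.append("<h2>Temporal summary images (criterion D)</h2>")
    for r in records:
        if r.summaries is not None:
            parts.append(_img_tag(summary_image_figure(r.summaries)))
    if mismatches:
        parts.append("<h2>Acquisition metadata mismatches</h2><ul>")
        for m in mismatches:
            if m.no_consensus:
                parts.append(f"<li>{html.escape(m.field_name)}: no consensus across runs</li>")
            else:
                dev = ", ".join(f"{rid} ({v!r})" for rid, v in m.deviants)
                parts.append(
                    f"<li>{html.escape(m.field_name)}: majority {m.majority_value!r}; "
                    f"deviant: {html.escape(dev)}</li>"
                )
        parts.append("</ul>")
    for r in records:
        if r.notes:
            parts.append(f"<p><b>{html.escape(r.run_id)} notes:</b> "
                         f"{html.escape(r.notes)}</p>")
    fmri_path = os.path.join(out_dir, "fmri_qc.html")
    with open(fmri_path, "w") as fh:
        fh.write(_PAGE.substitute(title="fMRI image QC", timestamp=stamp,
                                  body="\n".join(parts)))

    # --- behavior report
    parts = ["<h2>Decisions</h2>", _decision_table(decisions)]
    ev_list = [r.events for r in records if r.events is not None and r.behavior is not None]
    bh_list = [r.behavior for r in records if r.events is not None and r.behavior is not None]
    if ev_list:
        parts.append("<h2>Task presentation and performance (criteria B, C)</h2>")
        parts.append(_img_tag(behavior_figure(ev_list, bh_list)))
    msgs = [m for r in records if r.behavior is not None for m in r.behavior.messages]
    if msgs:
        parts.append("<h2>Notifications</h2><ul>")
        parts.extend(f"<li>{html.escape(m)}</li>" for m in msgs)
        parts.append("</ul>")
    behav_path = os.path.join(out_dir, "behavior_qc.html")
    with open(behav_path, "w") as fh:
        fh.write(_PAGE.substitute(title="Behavioral QC", timestamp=stamp,
                                  body="\n".join(parts)))

    # --- machine-readable decisions
    payload = {
        "schema_version": QC_SCHEMA_VERSION,
        "runs": [_full_record(r, d) for r, d in
                 zip(records, _aligned(decisions, records))],
    }
    json_path = os.path.join(out_dir, "qc_decisions.json")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"fmri": fmri_path, "behavior": behav_path, "decisions": json_path}


def _aligned(decisions: Sequence[QCDecision],
             records: Sequence[RunRecord]) -> list[QCDecision]:
    by_id = {d.run_id: d for d in decisions}
    return [by_id[r.run_id] for r in records]


def _full_record(r: RunRecord, d: QCDecision) -> dict[str, Any]:
    rec: dict[str, Any] = {"run_id": r.run_id, "decision": d.to_record()}
    if r.censor is not None:
        rec["motion"] = r.censor.to_record()
    if r.behavior is not None:
        rec["behavior"] = r.behavior.to_record()
    if r.overlap is not None:
        rec["trial_censor_overlap"] = {
            "n_trials_affected": r.overlap.n_trials_affected,
            "n_censored_in_trials": r.overlap.n_censored_in_trials,
            "n_censored_outside_trials": r.overlap.n_censored_outside_trials,
        }
    if r.summaries is not None:
        rec["image"] = {
            "n_frames_used": r.summaries.n_frames_used,
            "zero_sd_voxel_count": r.summaries.zero_sd_voxel_count,
        }
    if r.notes:
        rec["notes"] = r.notes
    return rec


def exclusion_summary(decisions: Sequence[QCDecision]) -> str:
    """Human-readable exit summary listing excluded runs and why."""
    lines = []
    for d in decisions:
        if not d.excluded:
            continue
        why = [name for name, v in
               [("A", d.criterion_a), ("B", d.criterion_b), ("C", d.criterion_c)]
               if v == "fail"]
        if d.criterion_d == "fail_by_override":
            why.append("D")
        lines.append(f"{d.run_id}: excluded (criterion {', '.join(why)})")
    if not lines:
        return "no runs excluded"
    return "\n".join(lines)
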