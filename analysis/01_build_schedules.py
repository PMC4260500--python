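#!/usr/bin/env python
"""Build the two session designs and verify their printed structure.

The within-task learning design alternates 15 theorem and 15 comic 45-s
study windows over three 11-minute episodes; the cross-task design runs
four tasks (n-back, reading span, subtraction and fraction word problems)
through three difficulty levels each in simple-to-complex order.  This
script counts the design quantities and writes them to
results/design_counts.json, plus one example event stream as TSV.
"""

import json
from pathlib import Path

import numpy as np

from wmlbci.schedules import build_study1_schedule, build_study2_session

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

s1 = build_study1_schedule("demo", 0)
windows = [e for e in s1.events if e.role == "study_window"]
counts = {
    "study1": {
        "theorem_windows": sum(e.task_id == "study1_theorem" for e in windows),
        "comic_windows": sum(e.task_id == "study1_comic" for e in windows),
        "total_windows": len(windows),
        "window_s": 45.0,
        "episode_duration_s": s1.total_duration_s / 3,
    }
}

s2 = build_study2_session("demo", 0)
nback_onsets = np.array([e.onset_s for e in s2.events
                         if e.role == "digit" and e.level == 1])
counts["study2"] = {
    "nback_isi_s": float(np.diff(nback_onsets).mean()),
    "letter_duration_s": {e.duration_s for e in s2.events if e.role == "letter"}.pop(),
    "fixation_duration_s": {e.duration_s for e in s2.events
                            if e.kind == "fixation" and e.task_id == "reading_span"}.pop(),
    "givens_per_problem": {len(e.payload["givens"]) for e in s2.events
                           if e.role == "fact"}.pop(),
    "levels_order_ok": all(
        [e.level for e in s2.events if e.task_id == t and e.kind == "stimulus"]
        == sorted(e.level for e in s2.events if e.task_id == t and e.kind == "stimulus")
        for t in ("nback", "reading_span", "subtraction", "fraction")
    ),
    "total_duration_min": s2.total_duration_s / 60,
}

(OUT / "design_counts.json").write_text(json.dumps(counts, indent=2))
s1_dir = OUT / "example_study1_session"
s1.to_files(s1_dir)
print(json.dumps(counts, indent=2))
print(f"\nwrote {OUT/'design_counts.json'} and example events under {s1_dir}/")
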