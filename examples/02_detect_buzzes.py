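"""Detect feeding buzzes in a synthetic echolocation recording.

Builds a call schedule mixing search-phase trains (6 ms calls, 200 ms
apart) with terminal buzzes (25 short calls at 7 ms intervals), renders
it as a log-amplitude envelope, and runs the full detection chain:
peak-picked calls with 5 dB endpoints, inter-pulse intervals, and the
buzz rule (>= 3 consecutive calls with IPIs < 10 ms).
"""

from batseg import detect_buzzes, detect_calls, generate_call_train
from batseg.simulate import calls_to_envelope

schedule = [("search", 0.0), ("buzz", 3.0), ("search", 5.0), ("buzz", 9.0)]
calls_true = generate_call_train("mixed", schedule=schedule)
t, amp = calls_to_envelope(calls_true, fs=40_000.0)

calls = detect_calls(t, amp, min_peak_db=10.0, min_sep=0.004)
buzzes = detect_buzzes(calls)

print(f"calls constructed : {len(calls_true)}")
print(f"calls detected    : {len(calls)}")
print(f"buzzes detected   : {len(buzzes)} (2 were scheduled)")
for b in buzzes:
    kind = "aborted" if b.aborted else "terminal"
    print(f"  t = {b.time:5.2f} s  {b.n_calls} calls  ({kind})")
print()
print("Each buzz marks a prey-capture attempt; a buzz followed by more")
print("search calls in the same recording is flagged as aborted.")
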