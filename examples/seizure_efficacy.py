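"""Score a treatment's seizure-reduction efficacy from LFP recordings.

Trains the EMD + higher-order-moment seizure detector on synthetic labeled
recordings, then scores a 'treated larva': a baseline recording with
frequent planted seizure bursts and a post-exposure recording with half as
many. The efficacy score is 1 - post/baseline frequency (0 = no change,
1.00 = seizure-free).
"""

from zfscreen.lfp import detect_seizures, efficacy_score, train_default_detector
from zfscreen.synth.lfp import simulate_lfp

detector = train_default_detector(seed=1)

baseline = simulate_lfp(600.0, event_times=[60, 130, 200, 270, 340, 410, 480, 550], seed=10)
post = simulate_lfp(600.0, event_times=[80, 230, 380, 530], seed=11)

calls_base = detect_seizures(baseline, detector)
calls_post = detect_seizures(post, detector)
print(f"baseline: {len(calls_base.events)} events detected "
      f"({calls_base.frequency:.1f} per 45 min); planted 8")
print(f"post:     {len(calls_post.events)} events detected "
      f"({calls_post.frequency:.1f} per 45 min); planted 4")

score = efficacy_score(calls_base, calls_post)
print(f"efficacy score: {score.score:.2f} "
      "(0 = unchanged, 1.00 = seizure-free; halving the frequency gives 0.50)")
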