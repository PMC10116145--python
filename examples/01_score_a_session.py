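"""Score a simulated VMT session and a PST response stream.

Builds a random stimulus, simulates a subject whose placement accuracy
improves over the five learning trials, and scores the session with the
discontinue rule; then scores a small PST stream against its key.
"""

from c3b import battery
from c3b.simulate import generate_vmt_responses

stim = battery.generate_vmt_stimulus(rng_seed=42)
print(f"stimulus: pattern {stim.pattern_id}, {len(stim.assignment)} symbols")

# a learner: 40% accurate on trial 1, perfect from trial 3 on
responses = generate_vmt_responses(stim, [0.4, 0.7, 1.0, 1.0, 1.0], seed=7)
result = battery.score_vmt_session([stim] * 5, responses)
print(f"trial scores: {result.trial_scores}")
print(f"discontinued after trial: {result.discontinued_after}")
print(f"session total (max 70): {result.total}")
# Two consecutive 14s trigger the discontinue rule; the remaining trials
# are allotted perfect scores and still count toward the total.

key = battery.generate_pst_key(rng_seed=42)
symbols = list(key.pairs)
items, presses = [], []
for i in range(40):
    sym = symbols[i % 9]
    t = 2.8 * (i + 1)  # one answer every 2.8 s
    digit = key.pairs[sym] if i % 10 else (key.pairs[sym] % 9 + 1)  # a few slips
    items.append(sym)
    presses.append((t, digit))
stream = battery.PSTResponseStream(items=tuple(items), presses=tuple(presses))
pst = battery.score_pst(key, stream)
print(f"PST within 120 s: {pst.n_correct} correct, {pst.n_incorrect} incorrect")
# Only presses with timestamp <= 120 s are scored, so the late answers in
# this stream are ignored.
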