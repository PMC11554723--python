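"""Score raw Corsi sessions: span, supraspan learning, delayed recall.

Builds a small trial-level session by hand and prints the three raw scores.
"""

from corsinorm import (
    CSSL_TARGET,
    SpanBlock,
    SpanSession,
    SupraspanSession,
    SupraspanTrial,
    score_span,
    score_supraspan_learning,
    score_supraspan_recall,
)

# Span: blocks of 3 target sequences; >= 2 exact reproductions pass a block.
blocks = [
    SpanBlock(2, targets=[(3, 7), (5, 2), (8, 4)], responses=[(3, 7), (5, 2), (8, 4)]),
    SpanBlock(3, targets=[(4, 1, 6), (9, 3, 5), (2, 8, 7)],
              responses=[(4, 1, 6), (9, 3, 5), (2, 8, 1)]),       # 2 of 3: passes
    SpanBlock(4, targets=[(6, 2, 9, 4), (1, 7, 3, 8), (5, 9, 2, 6)],
              responses=[(4, 9, 2, 6), (8, 3, 7, 1), (6, 2, 9, 5)]),  # 0 of 3: fails
]
span = score_span(SpanSession(blocks=blocks))
print(f"Corsi span (CS): {span}")
# -> 3: the longest block with at least two exact reproductions.

# Supraspan learning: partial credit per trial; three consecutive exact
# reproductions end the test and the remaining trials earn full credit.
trials = [
    SupraspanTrial((5, 8, 3, 2, 6, 4, 4, 4)),   # 5-cube ordered overlap
    SupraspanTrial(CSSL_TARGET),
    SupraspanTrial(CSSL_TARGET),
    SupraspanTrial(CSSL_TARGET),                # criterion met at trial 4
]
session = SupraspanSession(trials=trials)
cssl = score_supraspan_learning(session)
print(f"Supraspan learning (CSSL): {cssl:.2f}  (maximum 29.16)")
# -> 28.04 = 0.50 + 3*1.62 + 14*1.62 (unadministered trials credited).

# Delayed recall after five minutes, scored with the same partial-credit table.
cssr = score_supraspan_recall(SupraspanTrial(CSSL_TARGET))
print(f"Supraspan recall (CSSR): {cssr:.2f}  (maximum 1.62)")
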