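# Partial-credit scores for supraspan trial responses, by response category.
#
# The correct-response score (1.62) is fixed by the administration protocol;
# the intermediate values below are a SYNTHETIC fixture reflecting the
# chance-probability principle (rarer partial reproductions earn more), not
# published values.  Replace them with the protocol's official table for
# clinical use; the classifier categories are:
#   exact          - response identical to the 8-cube target
#   transposition  - target with exactly one pair of positions swapped
#   overlap_k      - longest ordered subsequence shared with the target has
#                    length k (k = 1..7)
#   none           - nothing reproduced in order (includes empty responses)
scores:
  exact: 1.62
  transposition: 0.90
  overlap_7: 1.00
  overlap_6: 0.75
  overlap_5: 0.50
  overlap_4: 0.30
  overlap_3: 0.18
  overlap_2: 0.10
  overlap_1: 0.06
  none: 0.0
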