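# Corsi span administration protocol: three target sequences per block,
# block lengths increasing from 2 to 9.
#
# The official target paths are distributed with the test's notation
# protocol and are not printed with the norms, so the sequences below are a
# SYNTHETIC editable fixture (valid paths on the 9-cube board, no repeated
# cube within a target).  Replace them with the official protocol sequences
# for clinical administration.  The length-8 block deliberately avoids the
# supraspan learning sequence 5-8-3-2-6-7-1-9.
blocks:
  - length: 2
    targets: ["3-7", "5-2", "8-4"]
  - length: 3
    targets: ["4-1-6", "9-3-5", "2-8-7"]
  - length: 4
    targets: ["6-2-9-4", "1-7-3-8", "5-9-2-6"]
  - length: 5
    targets: ["8-3-5-1-7", "2-6-4-9-3", "7-1-8-5-2"]
  - length: 6
    targets: ["4-8-2-7-5-9", "6-1-9-3-8-2", "3-5-7-2-4-1"]
  - length: 7
    targets: ["5-2-8-4-1-9-6", "7-3-6-9-2-5-8", "1-6-4-8-3-7-2"]
  - length: 8
    targets: ["2-9-5-3-8-1-6-4", "6-4-7-1-9-2-8-5", "9-1-3-6-2-8-4-7"]
  - length: 9
    targets: ["4-7-2-9-6-1-8-3-5", "8-5-1-4-7-3-9-6-2", "3-9-6-2-5-8-1-7-4"]
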