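# Example dictionary set. The green_pass rule is the canonical worked
# example: it fires on "tessera verde", "tessere verdi", "pass verde",
# "certificato verde" but not on "casa verde", "verderame", or
# "tessera del cinema".
- code: green_pass
  description: COVID-19 certificate (green pass) concept
  patterns:
    - '(tesser.\sverd.?|pass\sverd.?|certifica\w*\sverd.?)'
- code: vaccine
  description: vaccine concept
  patterns:
    - '\bvaccin\w*'
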