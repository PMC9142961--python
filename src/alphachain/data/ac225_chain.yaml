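# 225Ac serial decay chain with the half-lives used throughout the package.
# 221Fr is listed at 5 min; users preferring the literature value (4.8 min)
# can supply their own chain file.  213Bi branching (213Po/209Tl) is
# collapsed to one effective link; no counting window downstream of 213Bi
# is used, so the chain ends there (stable terminus implied).
nuclides:
  - {name: Ac-225, half_life: 9.9, unit: day}
  - {name: Fr-221, half_life: 5.0, unit: min}
  - {name: At-217, half_life: 32.3, unit: ms}
  - {name: Bi-213, half_life: 45.6, unit: min}
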