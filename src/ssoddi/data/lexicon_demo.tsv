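# Demonstration polarity lexicon (synthetic, hand-written for examples and
# tests; not derived from SentiWordNet). token<TAB>score in [-1, 1].
increase	-0.4
decrease	-0.3
reduce	-0.5
inhibit	-0.6
block	-0.5
potentiate	-0.5
toxicity	-0.9
toxic	-0.9
adverse	-0.8
risk	-0.6
dangerous	-0.9
bleeding	-0.8
fatal	-1.0
severe	-0.8
contraindicated	-0.9
avoid	-0.7
caution	-0.5
impair	-0.6
prolong	-0.4
accumulation	-0.5
interfere	-0.5
antagonize	-0.4
improve	0.7
enhance	0.3
benefit	0.8
beneficial	0.8
synergistic	0.6
effective	0.6
safe	0.8
well	0.5
tolerated	0.6
protective	0.7
therapeutic	0.5
efficacy	0.4
augment	0.2
moderate	-0.1
mild	0.2
minor	0.3
significant	-0.2
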