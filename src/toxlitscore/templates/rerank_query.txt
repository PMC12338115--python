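Does [compound] cause fatigue, jaundice, nausea or other liver toxicity symptoms?
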