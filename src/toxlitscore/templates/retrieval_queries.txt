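Does [compound] cause liver damage?
Does [compound] induce hepatotoxicity?
Does [compound] have hepatic effects?
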