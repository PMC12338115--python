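Is the compound "{compound}" known to you, i.e. can you describe what it is
and in which context it is used or studied?

A) Yes, I know this compound.
B) No, I do not know this compound.

Answer with a single letter.
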