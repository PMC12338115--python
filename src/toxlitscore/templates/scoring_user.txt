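Task: rate the risk of the compound below to cause liver injury in humans
on the following severity scale:

0) No known risk of liver injury.
1) Minimal risk: isolated or unconvincing reports of liver injury.
2) Moderate risk: documented cases of reversible liver injury.
3) High risk: well-documented cases of serious liver injury.
4) Severe risk: established cause of acute liver failure or death.

Context from the literature:
{context}

Compound: {compound}

Answer with a single digit from 0 to 4.
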