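"""Reading effect signs off GO term names.

GO names encode direction in a handful of cue words; a term like
"anti-apoptosis" acts against apoptosis, "pro-B cell differentiation"
promotes it.  Names with no cue ("regulation of apoptosis") are unsigned and
fall to a user policy.
"""

from goeffects import parse_effect_sign

NAMES = [
    "pro-B cell differentiation",
    "anti-apoptosis",
    "suppression of host defenses",
    "positive regulation of cell proliferation",
    "regulation of apoptosis",
    "antigen presentation",  # "anti" must not fire inside a word
]

for name in NAMES:
    print(f"{name!r:55s} -> {parse_effect_sign(name)}")

# +1 means the term promotes its process, -1 that it works against it, and
# "unsigned" that the name alone does not say.
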