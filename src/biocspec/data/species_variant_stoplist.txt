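# Variant stop-list: generated species-term variants whose lowercase form
# appears here are suppressed before they enter the matching dictionary.
# One entry per line; '#' starts a comment.  The list targets collisions
# between mechanically generated variants and ordinary English or
# biochemistry vocabulary (e.g. "kcat", the turnover number, generated by
# removing the space from the abbreviated cat-breed term "K cat").
kcat
camp
chip
cast
mark
white
spot
via
per
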