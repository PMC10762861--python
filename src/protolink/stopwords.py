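"""A small fixed English stop-word list for word-level tf-idf tokenization."""

ENGLISH_STOP_WORDS = frozenset(
    """
    a about above after again all am an and any are as at be because been
    before being below between both but by could did do does doing down
    during each few for from further had has have having he her here hers
    him his how i if in into is it its itself just me more most my no nor
    not of off on once only or other our ours out over own same she so some
    such than that the their theirs them then there these they this those
    through to too under until up very was we were what when where which
    while who whom why will with you your yours
    """.split()
)
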