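"""Zung self-rating scale item structure (SDS: depression, SAS: anxiety).

Both instruments have 20 four-point items (1 = occasionally/never ...
4 = continuous).  The listed items are reverse-keyed: they contribute
``5 - response`` to the total.
"""

N_ITEMS = 20

SDS_REVERSED = frozenset({2, 5, 6, 11, 12, 14, 16, 17, 18, 20})
SAS_REVERSED = frozenset({5, 9, 13, 17, 19})

REVERSED = {"SDS": SDS_REVERSED, "SAS": SAS_REVERSED}

ITEM_COLUMNS = [f"item_{i}" for i in range(1, N_ITEMS + 1)]
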