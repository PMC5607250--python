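"""Published per-library read-accounting counts used as a formatter fixture.

These are the raw counts of the dairy-goat mammary-gland two-library
small-RNA experiment this pipeline re-implements (early and late lactation,
libraries E and L): total raw reads and the reads absorbed by each filter
or contaminant class.  They serve as inputs to the accounting formatter --
feeding them through :func:`caprimir.contaminants.library_stats` must
reproduce the published percentages (e.g. 91.52% valid reads in E).
"""

PUBLISHED_ACCOUNTING = {
    "E": {
        "raw": 18_908_954,
        "junk": 4_227,
        "repeat": 38_984,
        "3adt_or_length": 1_197_580,
        "rRNA": 163_022,
        "tRNA": 73_643,
        "snoRNA": 43_634,
        "snRNA": 7_751,
        "other_ncRNA": 26_771,
        "mRNA": 85_700,
        "valid": 17_306_229,
    },
    "L": {
        "raw": 10_083_672,
        "junk": 4_886,
        "repeat": 25_990,
        "3adt_or_length": 1_851_160,
        "rRNA": 91_082,
        "tRNA": 38_858,
        "snoRNA": 15_082,
        "snRNA": 2_455,
        "other_ncRNA": 16_698,
        "mRNA": 62_242,
        "valid": 7_997_385,
    },
}


def published_stats(library: str):
    """Accounting table (counts + percentages of raw) for one library."""
    from .contaminants import library_stats

    counts = dict(PUBLISHED_ACCOUNTING[library])
    raw = counts.pop("raw")
    return library_stats(counts, raw)
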