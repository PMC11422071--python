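"""Published entire-collection (EC) reference summary for the orchid study.

The full 207-accession dataset is not packaged; these are the published
summary statistics of the entire collection, used as fixed inputs where a
quantity (e.g. the coincidence rate CR%) compares a recomputed core against
the published whole-collection spread.
"""

#: published EC summary per trait (n = 207)
PUBLISHED_EC_SUMMARY = {
    "flower_diameter": {
        "n": 207,
        "min": 2.9,
        "max": 14.0,
        "range": 11.1,
        "mean": 8.7,
        "sd": 2.7,
        "cv": 31.4,
    },
    "plant_height": {
        "n": 207,
        "min": 2.4,
        "max": 85.0,
        "range": 82.6,
        "mean": 49.2,
        "sd": 16.3,
        "cv": 33.2,
    },
}
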