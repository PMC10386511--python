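"""Reference tallies from the original annotated recordings.

These constants are inputs for validating the bookkeeping arithmetic
(clip-count totals, manual-vs-automatic comparison), not outputs of
this package: the per-category feature-video counts of the source
corpus, and the per-video (manually recorded, accurately recorded)
behavior counts of the 15-video manual-comparison study.
"""

#: feature-video count per behavior category in the source corpus
FEATURE_VIDEO_COUNTS = {
    "head": 269,
    "foreleg": 266,
    "fore-mid leg": 298,
    "mid-hind leg": 259,
    "hind leg": 272,
    "wing": 266,
    "0": 266,  # resting and walking, pooled
}

#: (n_manual, n_matched) per video of the manual-comparison study
MANUAL_COMPARISON_COUNTS = [
    (76, 67),
    (36, 31),
    (47, 43),
    (67, 60),
    (81, 73),
    (39, 35),
    (99, 88),
    (104, 88),
    (62, 55),
    (67, 60),
    (116, 95),
    (48, 41),
    (82, 72),
    (56, 48),
    (95, 86),
]
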