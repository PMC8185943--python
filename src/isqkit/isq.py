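"""Published constants for the Interoception Sensory Questionnaire (ISQ).

The 20-item ISQ uses a 7-point response scale.  The 8-item short form
(ISQ-8) retains items 1, 3, 4, 5, 9, 12, 15 and 20 and collapses the
response scale to 5 points by merging categories 2/3 and 5/6.

The generality ranking encodes, as an explicit configuration, the published
retain-the-more-general-item choices made during short-form construction
(e.g. item 3 over items 8/11/2, item 20 over items 19/7, item 5 over items
13/18, items 12 and 1 over item 17); content generality is a judgement
about item wording and cannot be computed from response data.
"""

#: published standardized loadings of the 20-item one-factor model; used by
#: the synthetic generator so simulated data reproduce the scale's
#: inter-item correlation regime (many pairs above 0.7)
ISQ20_LOADINGS = {
    "item1": 0.763, "item2": 0.606, "item3": 0.833, "item4": 0.673,
    "item5": 0.852, "item6": 0.867, "item7": 0.651, "item8": 0.789,
    "item9": 0.792, "item10": 0.890, "item11": 0.866, "item12": 0.837,
    "item13": 0.886, "item14": 0.887, "item15": 0.777, "item16": 0.877,
    "item17": 0.839, "item18": 0.837, "item19": 0.776, "item20": 0.717,
}

#: shared 7-to-5 response-category collapse map
ISQ_COLLAPSE_MAP = {1: 1, 2: 2, 3: 2, 4: 3, 5: 4, 6: 4, 7: 5}

#: items of the 8-item short form
ISQ8_ITEMS = ["item1", "item3", "item4", "item5",
              "item9", "item12", "item15", "item20"]

#: items in decreasing order of content generality
_ISQ_GENERALITY_ORDER = [
    "item3", "item20", "item5", "item1", "item12", "item4", "item9", "item15",
    "item2", "item6", "item7", "item8", "item10", "item11", "item13",
    "item14", "item16", "item17", "item18", "item19",
]

#: generality score per item (higher = more general, all distinct)
ISQ_GENERALITY = {item: float(len(_ISQ_GENERALITY_ORDER) - rank)
                  for rank, item in enumerate(_ISQ_GENERALITY_ORDER)}
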