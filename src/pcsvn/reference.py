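"""Published study-design constants used by the analysis scripts and tests.

Cohort feature statistics live in :data:`pcsvn.synthetic.COHORT_TARGETS`;
this module holds the remaining design numbers: cohort sizes, the CV fold
layout, and the per-component variance percentages of the study's
five-component loading table.
"""

N_HIGH_RISK = 89  # enriched-risk cohort placentas
N_LOW_RISK = 201  # population-based cohort placentas
N_TOTAL = N_HIGH_RISK + N_LOW_RISK

CV_FOLDS = 10

#: Percent of variance captured by each of the five retained principal
#: components in the published loading table (they sum to 88.63%).
PC_VARIANCE_PERCENT = (35.27, 22.57, 17.20, 7.79, 5.80)

#: Number of selected arterial attributes in the published ranking.
N_SELECTED_ARTERIAL = 15
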