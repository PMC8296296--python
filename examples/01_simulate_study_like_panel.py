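"""Generate the study-like daily panel and inspect its descriptive statistics.

The scenario emulates 242 days (1 Jan - 29 Aug 2020) of three daily series:
newly confirmed epidemic cases ("new", two outbreak waves), subway passenger
flow ("pas", weekday structure plus pandemic suppression, units of 10^4
passengers) and daily-mean PM2.5 ("pek", positive, winter-high seasonal
level), with 2% of cells missing at random.
"""

from tvpvarsv import StudyScenarioConfig, describe, impute_missing, make_study_like_panel

panel, baseline = make_study_like_panel(StudyScenarioConfig(seed=7))
print(f"panel: {panel.n_days} days x {panel.n_vars} variables, "
      f"{panel.missing_mask.sum()} missing cells")
print(f"dates {panel.dates[0].date()} .. {panel.dates[-1].date()}\n")

complete = impute_missing(panel, n_imputations=5, seed=7).consensus
print("descriptive statistics of the raw (imputed) panel:")
print(describe(complete).table.round(3))
print("\nEach row: observation count, mean, range and sample SD of one series.")
print("Observed epidemic counts are integers >= 0 (imputed cells are real-")
print("valued); passenger flow dips far below its normal-year level during")
print("the outbreak waves.")
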