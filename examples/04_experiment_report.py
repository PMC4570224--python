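"""Run a small multi-replicate experiment and print its aggregate report.

Uses the bd-5 study design (BD, s = 5) scaled down 10x (p = 1000, 3
replicates) so it finishes in about a minute; full-scale presets reproduce
the benchmark surfaces (sigma2_R vs sigma2_NL, n*/s, false-positive
histogram).
"""

import dataclasses
import json

from episense import study_presets, run_experiment

cfg = dataclasses.replace(study_presets()["bd-5"], scale=10, replicates=30, seed_base=1)
report = run_experiment(cfg)

print(f"config: {report.config_echo['name']}  (p={report.config_echo['p']}, "
      f"replicates={report.config_echo['replicates']})")
print(json.dumps(report.aggregates, indent=1, default=float))
print("""
fp_histogram           : share of replicates with 0/1/2/3/4-6 false positives
mean_sigma2_NL         : variance even an ideal linear model cannot explain
mean_sigma2_R          : variance the two-step quadratic fit leaves behind
median_n_star_over_support : typical samples needed per selected locus
""")
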