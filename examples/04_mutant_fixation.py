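"""Fixation of Wnt-activating mutations under wild-type vs autonomous Notch.

Seeds a single mutant stem cell per replicate and follows its clone until
it is fixed (sole lineage among stem cells) or lost.  mutant1 (raised
Paneth-contact requirement C1 = 4) over-produces Paneth cells and should
fix less often than a neutral label; mutant2 (additionally maintained
outside the niche, reduced contact inhibition, no Paneth migration bias)
should fix more often.  Reported as "fixations out of n mutations", the
neutral expectation being 1.

A censored mutant2 replicate is typically a clone still expanding: these
mutants take over nearly all stem-cell positions within weeks, but a few
contact-inhibited wild-type stem cells linger, so strict fixation (sole
lineage) resolves only on a multi-month horizon.
"""

import numpy as np

from cryptsim import replicate_experiment, scenario

HORIZON = 50 * 24.0  # 50 days, the comparison window used for mutants

for name in ("neutral_label", "mutant1_wild_type", "mutant2_wild_type"):
    exp = replicate_experiment(scenario(name), n_reps=8, seed=3, horizon=HORIZON)
    st = exp.fixation_statistics()
    n_sc = exp.mean_sc_count()
    print(f"{name}: fixed {st.n_fixed}, lost {st.n_lost}, "
          f"censored {st.n_censored} of {st.n_total}")
    if st.n_resolved:
        print(f"  fixation probability {st.fixation_probability:.2f}; "
              f"fixations per n = {st.fixations_per_n(round(n_sc)):.2f} "
              f"(n = {n_sc:.1f} SCs; neutral expectation 1.0)")
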