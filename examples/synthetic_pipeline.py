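"""Generate a synthetic quarterly SRS stream, anonymize it with every
algorithm variant, audit the releases with the full BFL attacker, and
compare information loss (NIL) and post-attack disclosure (DIR / DSR).

Expected picture: the single-release baseline (ms) has the least
information loss but leaks badly once releases are linked; the three
periodical variants audit clean, with ppms++ the least lossy of the
three (the full ppms++ <= ppms+ <= ppms ordering holds in expectation
over seeds, not necessarily in any single run).
"""

import numpy as np

from srsanon import (
    AnonymizerConfig,
    PrivacyParams,
    SynthConfig,
    ThresholdMap,
    VARIANTS,
    anonymize_series,
    audit_series,
    default_schema,
    dir_ratio,
    dsr_ratio,
    generate_series,
    nil,
)

cfg = SynthConfig(n_quarters=6, cases_per_quarter=400, followup_prob=0.3,
                  lifespan_max=4, max_symptom_prevalence=0.15, rng_seed=42)
schema = default_schema(cfg)
quarters = generate_series(cfg)
print(f"synthetic series: {[len(q) for q in quarters]} records per quarter "
      f"(2nd+ quarters include follow-ups of open cases)\n")

thresholds = ThresholdMap.uniform(0.4)
print(f"{'variant':8} {'mean NIL':>9} {'max DIR':>8} {'max DSR':>8}")
for variant in VARIANTS:
    params = PrivacyParams(k=5, thresholds=thresholds, lifespan_x=8, rng_seed=1)
    series, log = anonymize_series(schema, quarters,
                                   AnonymizerConfig(variant=variant, params=params))
    findings = audit_series(series)
    nils = [nil(schema, rel) for rel in series.releases if len(rel)]
    dirs = [dir_ratio(rel, i, findings, params.k) for i, rel in enumerate(series.releases)]
    dsrs = [dsr_ratio(rel, i, findings, thresholds) for i, rel in enumerate(series.releases)]
    print(f"{variant:8} {np.mean(nils):9.4f} {max(dirs):8.3f} {max(dsrs):8.3f}")

print("\nNIL is the normalized information loss in [0,1] (0 = nothing")
print("generalized).  DIR / DSR are the fractions of published groups in")
print("which the BFL attacker can break k-anonymity or a confidence bound;")
print("0 means the guarantee held in every release.")
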