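"""Agreement analysis between an automated and a manual measurement method.

Simulates 87 cases whose automated LA volumes differ from the expert values
by a small bias plus noise, then runs the full agreement stack: ICC (two-way,
absolute agreement, single measure) with 95% CI, Bland–Altman bias and limits
of agreement, and the proportional-bias slope test.
"""

import numpy as np
import pandas as pd

from atriometry import agreement_table, cohens_kappa, paired_time_test

rng = np.random.default_rng(2024)
n = 87
truth = rng.normal(95.0, 25.0, n)  # expert LA volumes, mL
auto = truth + rng.normal(0.9, 5.2, n)  # automated: small positive bias

df = pd.DataFrame(
    {
        "case_id": np.arange(n),
        "metric": "la_volume_ml",
        "value_auto": auto,
        "value_manual": truth,
    }
)
table = agreement_table(df)
row = table.iloc[0]
print(f"n = {row['n']}")
print(f"bias ± SD        : {row['bias']:+.2f} ± {row['sd']:.2f} mL")
print(f"limits of agreement: [{row['loa_lower']:.2f}, {row['loa_upper']:.2f}] mL")
print(f"ICC(A,1) [95% CI]  : {row['icc']:.3f} "
      f"[{row['icc_ci_lower']:.3f}, {row['icc_ci_upper']:.3f}]")
print(f"proportional bias p: {row['proportional_bias_p']:.3f}")

# time efficiency: automated ~0.5 min vs manual ~15 min per case
manual = rng.normal(15.3, 1.4, n)
automated = rng.normal(0.5, 0.1, n)
t = paired_time_test(automated, manual)
print(f"time comparison    : {t.test}-test, p = {t.pvalue:.2e}")

# inter-rater usability grades
rater1 = rng.choice(list("AAB"), n)
agree = rng.random(n) < 0.9
rater2 = np.where(agree, rater1, rng.choice(list("ABC"), n))
print(f"Cohen's kappa      : {cohens_kappa(rater1, rater2):.2f}")
# An ICC near 1 with narrow LOA means the automated method can replace the
# manual one; a significant proportional-bias p would indicate the error
# grows with chamber size.
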