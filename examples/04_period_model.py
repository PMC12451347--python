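"""Random-intercept period model: recover an injected Ramadan-window shift.

Each subject contributes one value per 30-day window; a subject-specific
random intercept absorbs between-subject level differences and the five
windows enter as a categorical fixed effect with window -2 as reference.
"""

import numpy as np
import pandas as pd

from vkawindows import fit_period_model, summarize_metric

rng = np.random.default_rng(3)
n, delta = 400, 2.0
windows = [-2, -1, 0, 1, 2]
b = rng.normal(0, 5, n)  # subject levels
rows = [
    {"subject_id": i, "window": w, "value": b[i] + (delta if w == 0 else 0.0) + rng.normal(0, 3)}
    for i in range(n)
    for w in windows
]
df = pd.DataFrame(rows)

res = fit_period_model(df)
print(res.effects.round(3).to_string(index=False))
print(f"variance components: subject {res.var_subject:.2f}, residual {res.var_residual:.2f}")
# The window-0 estimate should sit near the injected +2.0 with a Wald CI
# of roughly +/-0.4; all other windows near zero.

print(summarize_metric(df).round(2).to_string(index=False))
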