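"""Size-dependent test sensitivity and a one-time screening exam.

Prints the default colonoscopy sensitivity curve at its anchor sizes,
then screens a small simulated cohort once at ages 55-64 with flexible
sigmoidoscopy and reports the sex-specific cancer detection rates.
"""

import numpy as np

from crccal import colonoscopy_model, sigmoidoscopy_model, simulate_population
from crccal.synthetic_study import DEFAULT_TRUTH
from crccal.targets import screen_detection_rates

model = colonoscopy_model()
print("colonoscopy sensitivity by adenoma size:")
for size in (1, 5, 7.5, 10, 15, 20):
    print(f"  {size:>4} mm: adenoma {model.adenoma_sensitivity(size):.3f}, "
          f"preclinical cancer {model.preclinical_sensitivity(size):.3f}")

rng = np.random.default_rng(42)
n = 20000
pop = simulate_population(DEFAULT_TRUTH, n, rng, horizon=64.0)
screen_age = rng.uniform(55.0, 64.0, n)
rates = screen_detection_rates(pop, screen_age, sigmoidoscopy_model(), rng)
print(f"\none-time sigmoidoscopy at ages 55-64 ({n} agents):")
print(f"  men:     {rates['male']:.4f}")
print(f"  women:   {rates['female']:.4f}")
print(f"  overall: {rates['overall']:.4f}")

# The rates are the expected proportion of screened, cancer-free people
# in whom a preclinical cancer is found; the overall rate is the
# person-count-weighted average of the sex-specific rates.
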