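"""Simulate individual colorectal-cancer natural histories.

Builds a small cohort with the package's default ground-truth
parameters and prints each component of the disease pathway for the
first agent who develops clinical cancer: adenoma initiations, growth
to 10 mm, malignant transition, sojourn time and clinical detection.
"""

from crccal import AgentSpec, mean_sojourn_time, simulate_agent
from crccal.synthetic_study import DEFAULT_TRUTH

params = DEFAULT_TRUTH
print(f"colon mean sojourn time:  {mean_sojourn_time(params, 'colon'):.2f} years")
print(f"rectum mean sojourn time: {mean_sojourn_time(params, 'rectum'):.2f} years")
print()

for agent_id in range(500):
    history = simulate_agent(AgentSpec(agent_id, agent_id % 2), params, master_seed=7)
    if history.clinical_crc_age is None:
        continue
    sex = "female" if history.spec.female else "male"
    print(f"agent {agent_id} ({sex}), dies of other causes at "
          f"{history.death_age_other_cause:.1f}")
    for lesion in history.adenomas:
        line = (f"  {lesion.location:<6} adenoma at age {lesion.init_age:.1f}, "
                f"reaches 10mm after {lesion.t_10mm:.1f}y")
        if lesion.transition_age is not None:
            line += (f"; becomes cancer at {lesion.transition_age:.1f} "
                     f"({lesion.transition_size:.1f}mm), sojourn "
                     f"{lesion.sojourn_time:.1f}y")
        print(line)
    print(f"  first clinical cancer at age {history.clinical_crc_age:.1f}")
    break

# The printed history traces one simulated person through the
# adenoma-carcinoma sequence; ages are in years, diameters in mm.
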