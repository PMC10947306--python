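"""Power of a planned 10-trial IPD meta-analysis to detect a treatment-sex interaction.

Uses only published aggregate data (participants, events and the percentage
of males per arm for each trial). The assumed minimally important interaction
is a hazard ratio of 1.3 for males versus females; weights use option (i),
which needs no follow-up information.
"""

import math

from ipdma_power import Scenario, load_antihypertensive_example, run_power_analysis

trials = load_antihypertensive_example("sex")
scenario = Scenario(lambda_target=math.log(1.3), wij_option="i", alpha=0.05)
result = run_power_analysis(trials, scenario)

print("trial  var(interaction)  power alone (%)  weight (%)")
for t in result.per_trial:
    print(f"{t.trial_id:>5}  {t.var_lambda_scaled:16.4g}  {100 * t.trial_power:15.2f}"
          f"  {100 * t.weight:10.2f}")
print(f"\npooled variance of the summary interaction: {result.pooled_var:.4g}")
print(f"power of the meta-analysis: {100 * result.power:.1f}%")
print("\nEach trial alone is badly underpowered (5-28%); pooling all ten trials'")
print("interaction estimates lifts the power to detect HR 1.3 to about 74%.")
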