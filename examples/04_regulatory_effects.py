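"""Rank regulators by how much their regulatory effect changes.

The regulatory effect sums path products (length <= 2) from a
regulator to the target in each sample's network; its max-minus-min
spread across samples flags regulators whose influence the modulator
switches on or off.
"""

from vcgrn import (
    effect_change,
    effect_profile,
    generate_switch_scenario,
    infer_networks,
)

scn = generate_switch_scenario(n_samples=200, n_regulators=12,
                               noise_sd=0.3, seed=3)
ens = infer_networks(scn.expr, scn.regulator_index, ["TGT"],
                     scn.modulator, h=0.2)

profile = effect_profile(ens, "TGT", max_path_length=2)
table = effect_change(profile, method="max_min")

print("regulator  type  effect_change  rank")
for reg, row in table.table.sort_values("rank").head(5).iterrows():
    print(f"{reg:<9}  {row.mode_label:<4}  {row.change:13.4f}  {row['rank']:4d}")

print(f"\nPlanted switching regulator: {scn.truth['switching_regulator']}.")
print("Its effect moves from ~0 to ~1 along the modulator (change ~1),")
print("while decoy regulators show only noise-level changes; 'A' marks an")
print("activator (largest-magnitude effect positive), 'I' an inhibitor.")
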