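"""Primary (full-stratum) vs nonoverlap control selection, side by side.

The primary analysis lets control windows overlap each other; the sensitivity
analysis tiles discrete 3-day controls instead. Estimates should agree in
sign for a genuinely planted effect.
"""

from flarecc import RunConfig, SimConfig, run_sensitivity

config = RunConfig(
    simulation=SimConfig(
        n_participants=200, seed=21, planted_effects=[("anxiety", "mean", 0.7)]
    ),
    definitions=("at",),
)
primary, nonoverlap, comparison = run_sensitivity(config)

n_full = (primary.windows["label"] == "control").sum()
n_non = (nonoverlap.windows["label"] == "control").sum()
print(f"control windows: {n_full} full-stratum vs {n_non} nonoverlap\n")

rows = comparison[comparison["exposure"] == "anxiety"]
for _, r in rows.iterrows():
    print(
        f"  anxiety {r['metric']:>4s} ({r['model_type']:>13s}): "
        f"OR {r['or_primary']:5.2f} [{r['ci_low_primary']:.2f}, {r['ci_high_primary']:.2f}]"
        f"  vs  {r['or_nonoverlap']:5.2f} [{r['ci_low_nonoverlap']:.2f}, {r['ci_high_nonoverlap']:.2f}]"
    )
print(
    "\nLeft: primary analysis; right: nonoverlap controls. Fewer controls"
    "\nwiden the intervals but the direction of association is stable."
)
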