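"""Generate a synthetic administrative radiotherapy record set.

Each row is one daily treatment fraction; the latent therapeutic role
(curative C / palliative P) drives the regimen: palliative courses are
short with large dose per fraction, curative courses long with ~200 cGy
fractions. The recorded intent is a noisy, partly missing copy of the
truth — exactly the data-quality problem the classifier addresses.
"""

from radrole import SynthConfig, generate_records

config = SynthConfig(n_patients=1000, seed=7)
df = generate_records(config)

print(f"{len(df)} daily records for {config.n_patients} patients")
print(f"palliative record share: {(df.true_role == 'P').mean():.1%} (target 14%)")
for role in ("C", "P"):
    sub = df[df.true_role == role]
    print(
        f"role {role}: median fraction size {sub.fraction_size.median():.0f} cGy, "
        f"median days from first treatment {sub.days_from_first.median():.0f}"
    )
print(f"intent missing: {df.intent_flag.isna().mean():.1%} (configured 18.8%)")
present = df[df.intent_flag.notna()]
print(f"intent wrong when present: {(present.intent_flag != present.true_role).mean():.1%} "
      "(configured 4%)")
print("\nThe medians mirror the reference profile: palliative fractions are "
      "larger, and curative records sit later in their (longer) courses.")
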