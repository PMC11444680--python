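"""Generate a synthetic pre-/post-therapy lipidomics cohort.

The default spec emulates the study design: 48 patients sampled before
paclitaxel therapy (day 1), 31 of them again after (day 2), 255 quantified
lipid mediators, 17/31 post-therapy patients neuropathy-positive, log-normal
concentrations with ~5% values missing completely at random.
"""

from lipidpanel import SyntheticSpec, generate, generate_second_cohort

spec = SyntheticSpec(seed=0)
ds, truth = generate(spec)

print(f"primary cohort: {ds.shape[0]} samples x {ds.shape[1]} lipid mediators")
print(f"  day 1 samples: {(ds.timepoint == 'day1').sum()}")
print(f"  day 2 samples: {(ds.timepoint == 'day2').sum()}")
print(f"  neuropathy-positive on day 2: {(ds.neuropathy == 'yes').sum()}")
print(f"  missing cells: {int(ds.values.isna().sum().sum())}")
print(f"  time-informative markers (ground truth): {len(truth.time_features)}")
print(f"    e.g. {truth.time_features[:3]}")

external = generate_second_cohort(spec, truth, attenuation=0.5)
print(f"external cohort: {external.shape[0]} samples x "
      f"{external.shape[1]} mediators (attenuated effects)")

# The ground truth lists which features carry real class differences, so any
# selector's sensitivity/specificity is measurable on this cohort.
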