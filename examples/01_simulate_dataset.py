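"""Generate a synthetic behavioural screen with known ground truth.

Two strains (wild-type N2 reference and one mutant) are tracked over three
independent days, five wells per strain per day, with 200 features per
recording window.  Ten percent of features carry a true strain effect of
2 standard deviations; wells tracked on the same day share a day-block
random effect.
"""

from phenoscreen import SimulationConfig, simulate_feature_dataset

config = SimulationConfig(
    n_strains=2,
    wells_per_strain_per_day=5,
    n_days=3,
    n_features_per_window=200,
    affected_fraction=0.10,
    effect_size_dist={"name": "fixed", "value": 2.0},
    sigma_day=0.5,
    sigma_well=1.0,
    nan_rate=0.05,
    rng_seed=1,
)

tables, metadata, truth = simulate_feature_dataset(config)

print(f"wells: {len(metadata)}  (strains: {sorted(metadata['strain'].unique())})")
print(f"features per window: {tables['prestim'].shape[1]}")
print(f"missing entries in prestim window: {int(tables['prestim'].isna().sum().sum())}")
print(f"features with a true injected effect: {len(truth)}")
print("\nfirst ground-truth effects (feature units, i.e. multiples of sigma_well):")
print(truth.head().to_string(index=False))
# Each listed (strain, feature) pair differs from N2 by `true_effect` on
# average; everything else differs only through day and well noise.
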