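"""Generate a synthetic three-cohort GWAS study with a known causal chain.

Builds independent exposure / mediator / outcome cohorts in which the
exposure raises the mediator (theta_xm = 0.3), the mediator raises the
log-odds of the binary outcome (theta_my = 0.4), and the exposure also acts
directly (theta_xy = 0.1), then summarizes each cohort per SNP.
"""

from mrchain import SimulationConfig, simulate_study

config = SimulationConfig(
    n_exposure=3757,      # exposure GWAS cohort size
    n_mediator=8299,      # mediator GWAS cohort size
    n_outcome=20_000,     # outcome (case-control) cohort size
    m_snps=200,
    n_causal=25,
    n_causal_mediator=25,
    theta_xm=0.3,
    theta_my=0.4,
    theta_xy=0.1,
    outcome_prevalence=0.1,
    seed=7,
)
study = simulate_study(config)

for name, stats in [
    ("exposure", study.exposure_stats),
    ("mediator", study.mediator_stats),
    ("outcome", study.outcome_stats),
]:
    hits = int((stats["P"] < 1e-5).sum())
    print(f"{name:9s}: {len(stats)} SNPs summarized, {hits} below P < 1e-5")
print(f"LD table: {len(study.ld_table)} within-window pairs")
print(f"true total exposure->outcome effect (log-odds): {study.truth['beta_total']:.3f}")

# The exposure and mediator each have their own suggestive instruments; the
# binary outcome, as expected for a modest case count, has few or none - which
# is exactly why the reverse-MR screen often cannot run at desk scale.
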