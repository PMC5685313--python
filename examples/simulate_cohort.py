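"""Generate a synthetic bariatric-surgery cohort and inspect it.

The generator emulates the structure of the real (controlled-access)
study data: Table-1-style pre-surgery covariates with missingness, an
LD-blocked SNP panel annotated to genes, a gene-interaction network,
and remission labels from a logistic model with planted clinical and
genetic effects.
"""

from remission_rank import simulate_study

gm, cohort, annotation, ppi, effects = simulate_study(
    n_samples=457, n_snps=400, seed=42)

print(f"patients: {gm.n_samples}, SNPs: {gm.n_snps}, "
      f"genes: {ppi.number_of_nodes()}, interactions: {ppi.number_of_edges()}")
print(f"remitters: {int(cohort.remission.sum())} "
      f"({cohort.remission.mean():.1%}) — the study cohort had 317/457 (69%)")
print(f"planted clinical effects (log-odds): {effects.clinical_effects}")
print(f"planted SNP effects (per minor allele): "
      f"{ {s: round(b, 2) for s, b in effects.causal_snps.items()} }")
print(f"network-latent SNP (suppressed marginal signal): "
      f"{effects.network_latent_snps[0]}")
print("\ncovariate missingness per column:")
print(cohort.data.isna().mean().loc[lambda s: s > 0].round(3).to_string())
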