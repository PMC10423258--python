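"""Bulk pipeline walkthrough: expression -> activity scores -> bounds ->
medium -> quadratic-programming FBA.

Builds a small toy metabolic network and a synthetic TPM-like expression
matrix, then estimates one flux vector per sample.  Fluxes are relative
scores on a [-1, 1] bound scale: negative exchange flux = nutrient uptake,
positive = secretion, and the biomass flux summarises how much growth the
expression state supports under the given nutrient medium.
"""

import tmeflux as tf

model = tf.make_toy_gem(
    tf.ToyGEMSpec(n_internal_metabolites=3, n_exchange_metabolites=3,
                  n_reactions=12, fraction_reversible=0.4, seed=3)
)
print(f"toy model: {model.n_reactions} reactions, {model.n_metabolites} "
      f"metabolites, {len(model.exchange_reactions)} exchanges, "
      f"{len(model.r1)} enzyme-associated (R1)")

expr = tf.make_synthetic_expression(model, n_samples=3, noise_sd=0.3, seed=4)
medium = tf.MediumProfile("full", frozenset(model.exchange_metabolites()))

flux = tf.run_bulk_pipeline(expr, model, medium)
print(f"\nflux table: {flux.shape[0]} reactions x {flux.shape[1]} samples")

bio = flux.iloc[model.biomass_reaction]
print("\nbiomass flux per sample (higher = more growth supported):")
for s, v in bio.items():
    print(f"  {s}: {v:.4f}")

print("\nexchange fluxes, sample0 (negative = uptake, positive = secretion):")
fv = tf.FluxVector(model.reaction_ids, flux["sample0"].to_numpy())
for met in sorted(model.exchange_metabolites()):
    v = tf.exchange_flux(fv, model, met)
    print(f"  {met}: {v:+.4f}  ({tf.classify_direction(v)})")
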