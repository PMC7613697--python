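# Default intervention specifications: vitamin A capsule doses and the
# standard wheat-flour fortificants with their assumed bioavailability.
capsules:
  dose_100k_mcg: 30000   # 100K IU capsule, mcg retinol
  dose_200k_mcg: 60000   # 200K IU capsule, mcg retinol

fortificants:
  vitamin_a:
    compound: retinol
    level_mg_per_kg: 3.0
    bioavailability_fraction: 1.0
  iron:
    compound: NaFeEDTA
    level_mg_per_kg: 35.0
    bioavailability_fraction: 0.10
  zinc:
    compound: zinc_oxide
    level_mg_per_kg: 30.0
    bioavailability_fraction: 0.30
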