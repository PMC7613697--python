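# Country-specific composition override rules.
#
# These ship as editable configuration rather than code: adding a new
# override (or changing the membership of a country list) requires no code
# change.  The default rules implement the two standard adjustments for
# national food supplies:
#
#   * In Sub-Saharan African countries of the tropical rain belt, roughly 70%
#     of palm oil production retained for domestic consumption is consumed
#     unrefined as red palm oil, which is rich in provitamin A carotenoids.
#     Exports, imports and production elsewhere are refined (vitamin A ~ 0).
#   * In Bangladesh, rice is consumed almost exclusively as parboiled,
#     polished white rice, so the rice composition record is replaced by a
#     parboiled-white-only record for all Bangladeshi flows.
#
# The tropical-rain-belt membership list is an editable assumption: the
# source literature does not enumerate the countries.

country_lists:
  tropical_belt_ssa:
    - NGA
    - GHA
    - CIV
    - CMR
    - COD
    - COG
    - GAB
    - GNQ
    - LBR
    - SLE
    - GIN
    - GNB
    - BEN
    - TGO
    - CAF
    - UGA
    - TZA
    - AGO

rules:
  - name: red_palm_oil_domestic
    fc_code: palm_oil
    countries: {list_ref: tropical_belt_ssa}
    flow_roles: [domestic_retained]
    action: {type: blend, variant: red_palm, weight: 0.70}
  - name: bangladesh_parboiled_rice
    fc_code: rice
    countries: {list: [BGD]}
    flow_roles: [domestic_retained, export, import]
    action: {type: replace, variant: parboiled_white}
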