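# Expert weight hierarchy for the Yicheng City evaluation, transcribed as
# printed from the published weight table.  Groups whose printed child
# weights do not sum to 1 carry the "non-normalized" flag (they are kept
# as printed; call WeightTree.normalized() for a usable tree).
# "quality_grade_of_air" is realigned from the water block to the
# atmospheric block, where the printed weights sum to exactly 1.00;
# population_intensity has no printed weight and carries 0, flagged.
id: eco_sensitivity
weight: 1.0
children:
  - id: soil_conditions
    weight: 0.26
    children:
      - id: soil_water_loss
        weight: 0.2
        children:
          - {id: rainfall_erosion, weight: 0.2}
          - {id: vegetation_type, weight: 0.2}
          - {id: slope, weight: 0.25}
          - {id: soil_texture, weight: 0.35}
      - id: soil_quality
        weight: 0.32
        flags: [non-normalized]   # printed child weights sum to 1.02
        children:
          - {id: soil_type, weight: 0.24}
          - {id: landform, weight: 0.18}
          - {id: ph, weight: 0.18}
          - {id: hg, weight: 0.09}
          - {id: zn, weight: 0.09}
          - {id: ni, weight: 0.08}
          - {id: hchs, weight: 0.08}
          - {id: groundwater_depth, weight: 0.08}
      - id: land_use_cover
        weight: 0.28
      - id: land_use_intensity
        weight: 0.2
  - id: water_conditions
    weight: 0.24
    flags: [non-normalized]       # printed child weights sum to 0.88
    children:
      - id: water_quality
        weight: 0.25
        flags: [non-normalized]   # printed child weights sum to 1.12
        children:
          - {id: water_sort, weight: 0.55}
          - {id: bod, weight: 0.12}
          - {id: cod_mn, weight: 0.11}
          - {id: ammonia_nitrogen, weight: 0.11}
          - {id: cr6, weight: 0.11}
          - {id: water_supply_function, weight: 0.12}
      - id: water_exchange_intensity
        weight: 0.18
      - id: distance_to_water
        weight: 0.23
      - id: protection_layer_quality
        weight: 0.22
  - id: atmospheric_conditions
    weight: 0.23
    children:
      - {id: quality_grade_of_air, weight: 0.28, flags: [realigned-from-water-block]}
      - {id: so2, weight: 0.14}
      - {id: no2, weight: 0.13}
      - {id: tsp, weight: 0.12}
      - {id: pm10, weight: 0.11}
      - {id: gas_disposal_ratio, weight: 0.10}
      - {id: pollution_burden, weight: 0.12}
      - {id: population_intensity, weight: 0.0, flags: [no-printed-weight]}
  - id: biodiversity
    weight: 0.27
    children:
      - id: abiotic_environment
        weight: 0.28
        children:
          - {id: annual_mean_temperature, weight: 0.48}
          - {id: annual_rainfall, weight: 0.52}
      - id: biological_abundance
        weight: 0.38
        children:
          - {id: protected_wildlife, weight: 0.31}
          - {id: vegetation_cover, weight: 0.42}
          - {id: biodiversity_index, weight: 0.27}
      - id: socioeconomic_development
        weight: 0.34
        children:
          - {id: fixed_assets_investment, weight: 0.18}
          - {id: net_income, weight: 0.18}
          - {id: engel_coefficient, weight: 0.47}
          - {id: urbanization_level, weight: 0.17}
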