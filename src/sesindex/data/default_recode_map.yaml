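# Default dichotomization map for the 16 candidate housing/asset items.
# 1 always indicates the higher-SES state. Category conventions for water,
# sanitation, flooring and fuel follow WHO/UNICEF JMP-style groupings
# (improved water source, flush/pour-flush sanitation, finished floor,
# clean cooking fuel); every mapping is user-overridable.
items:
  finished_floor:
    source: floor_material
    type: categorical
    map:
      cement: 1
      concrete: 1
      tile: 1
      ceramic_tile: 1
      vinyl: 1
      carpet: 1
      polished_wood: 1
      parquet: 1
      earth: 0
      sand: 0
      dung: 0
      wood_planks: 0
      palm_bamboo: 0
  flush_toilet:
    source: sanitation_facility
    type: categorical
    map:
      flush: 1
      pour_flush: 1
      pit_latrine: 0
      ventilated_pit_latrine: 0
      composting_toilet: 0
      bucket: 0
      open_defecation: 0
      none: 0
  lpg_electricity_fuel:
    source: cooking_fuel
    type: categorical
    map:
      lpg: 1
      electricity: 1
      natural_gas: 1
      biogas: 1
      kerosene: 0
      charcoal: 0
      wood: 0
      crop_residue: 0
      dung: 0
      coal: 0
  improved_water:
    source: water_source
    type: categorical
    map:
      piped_dwelling: 1
      piped_yard: 1
      public_tap: 1
      tubewell_borehole: 1
      protected_well: 1
      protected_spring: 1
      rainwater: 1
      bottled: 1
      unprotected_well: 0
      unprotected_spring: 0
      tanker: 0
      surface_water: 0
  more_than_one_room:
    source: rooms_in_home
    type: count
    rule: {op: ge, value: 2}
  small_household:
    source: people_in_home
    type: count
    rule: {op: le, value: 4}
  bicycle: {source: bicycle, type: binary}
  motorbike: {source: motorbike, type: binary}
  car: {source: car, type: binary}
  truck_tractor: {source: truck_tractor, type: binary}
  electricity: {source: electricity, type: binary}
  television: {source: television, type: binary}
  refrigerator: {source: refrigerator, type: binary}
  computer: {source: computer, type: binary}
  flip_phone: {source: flip_phone, type: binary}
  smart_phone: {source: smart_phone, type: binary}
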