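# Scenario speed model: travel speed (km/h) and locomotion mode per
# friction-surface class.  Water bodies are barriers (speed 0) in every
# scenario.  Scenario 1: walking everywhere.  Scenario 2: walking off-road,
# cycling on roads.  Scenario 3: walking off-road and on rural/feeder roads,
# minibus on national and district roads (inside the transit mask).
classes:
  1:  {name: mosaic_cropland_shrub_grass, category: landcover}
  2:  {name: shrub_cover_open_closed, category: landcover}
  3:  {name: regularly_flooded_shrub_herbaceous, category: landcover}
  4:  {name: sparse_herbaceous_shrub, category: landcover}
  5:  {name: tree_broadleaved_deciduous_open, category: landcover}
  6:  {name: artificial_areas, category: landcover}
  7:  {name: mosaic_cropland_tree_natural_veg, category: landcover}
  8:  {name: tree_needleleaved_evergreen, category: landcover}
  9:  {name: cultivated_managed, category: landcover}
  10: {name: mosaic_tree_natural_veg, category: landcover}
  11: {name: water_bodies, category: water}
  12: {name: tree_broadleaved_evergreen, category: landcover}
  13: {name: herbaceous_closed_open, category: landcover}
  14: {name: road_national, category: road}
  15: {name: road_district, category: road}
  16: {name: road_rural_feeder, category: road}
scenarios:
  1:
    1:  {speed: 1.67, mode: walk}
    2:  {speed: 1.67, mode: walk}
    3:  {speed: 1.0,  mode: walk}
    4:  {speed: 2.5,  mode: walk}
    5:  {speed: 1.25, mode: walk}
    6:  {speed: 5.0,  mode: walk}
    7:  {speed: 1.67, mode: walk}
    8:  {speed: 1.67, mode: walk}
    9:  {speed: 1.67, mode: walk}
    10: {speed: 1.25, mode: walk}
    11: {speed: 0.0,  mode: null}
    12: {speed: 1.0,  mode: walk}
    13: {speed: 1.67, mode: walk}
    14: {speed: 5.0,  mode: walk}
    15: {speed: 5.0,  mode: walk}
    16: {speed: 5.0,  mode: walk}
  2:
    1:  {speed: 1.67, mode: walk}
    2:  {speed: 1.67, mode: walk}
    3:  {speed: 1.0,  mode: walk}
    4:  {speed: 2.5,  mode: walk}
    5:  {speed: 1.25, mode: walk}
    6:  {speed: 5.0,  mode: walk}
    7:  {speed: 1.67, mode: walk}
    8:  {speed: 1.67, mode: walk}
    9:  {speed: 1.67, mode: walk}
    10: {speed: 1.25, mode: walk}
    11: {speed: 0.0,  mode: null}
    12: {speed: 1.0,  mode: walk}
    13: {speed: 1.67, mode: walk}
    14: {speed: 10.0, mode: bicycle}
    15: {speed: 10.0, mode: bicycle}
    16: {speed: 10.0, mode: bicycle}
  3:
    1:  {speed: 1.67, mode: walk}
    2:  {speed: 1.67, mode: walk}
    3:  {speed: 1.0,  mode: walk}
    4:  {speed: 2.5,  mode: walk}
    5:  {speed: 1.25, mode: walk}
    6:  {speed: 5.0,  mode: walk}
    7:  {speed: 1.67, mode: walk}
    8:  {speed: 1.67, mode: walk}
    9:  {speed: 1.67, mode: walk}
    10: {speed: 1.25, mode: walk}
    11: {speed: 0.0,  mode: null}
    12: {speed: 1.0,  mode: walk}
    13: {speed: 1.67, mode: walk}
    14: {speed: 50.0, mode: motorized}
    15: {speed: 20.0, mode: motorized}
    16: {speed: 5.0,  mode: walk}
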