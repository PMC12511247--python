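# Default allometric coefficient tables: biomass = a * diameter^b
# (kg dry matter, diameter in cm), CWD wood densities in g cm^-3.
#
# source: literature-to-be-filled
# These defaults are PLACEHOLDERS with realistic magnitudes for Interior
# Alaska species; replace them with coefficients from the published
# species-specific allometry you intend to apply before interpreting real
# field data.  All package tests use synthetic truth tables, so results on
# synthetic campaigns do not depend on these values.

deciduous_species:
  - "Populus tremuloides"
  - "Betula neoalaskana"
  - "Populus balsamifera"

trees:
  "Picea mariana":
    stem:            {a: 0.100, b: 2.30}
    bark:            {a: 0.020, b: 2.20}
    coarse_branches: {a: 0.020, b: 2.20}
    fine_branches:   {a: 0.010, b: 2.00}
    foliage:         {a: 0.012, b: 1.80}
    cones:           {a: 0.002, b: 1.50}
  "Picea glauca":
    stem:            {a: 0.105, b: 2.30}
    bark:            {a: 0.020, b: 2.20}
    coarse_branches: {a: 0.020, b: 2.20}
    fine_branches:   {a: 0.010, b: 2.00}
    foliage:         {a: 0.012, b: 1.80}
    cones:           {a: 0.002, b: 1.50}
  "Populus tremuloides":
    stem:            {a: 0.110, b: 2.25}
    bark:            {a: 0.025, b: 2.15}
    coarse_branches: {a: 0.018, b: 2.15}
    fine_branches:   {a: 0.008, b: 2.00}
    foliage:         {a: 0.010, b: 1.70}
    cones:           {a: 0.000001, b: 1.00}
  "Betula neoalaskana":
    stem:            {a: 0.108, b: 2.25}
    bark:            {a: 0.024, b: 2.15}
    coarse_branches: {a: 0.018, b: 2.15}
    fine_branches:   {a: 0.008, b: 2.00}
    foliage:         {a: 0.010, b: 1.70}
    cones:           {a: 0.000001, b: 1.00}
  default:
    stem:            {a: 0.100, b: 2.30}
    bark:            {a: 0.020, b: 2.20}
    coarse_branches: {a: 0.020, b: 2.20}
    fine_branches:   {a: 0.010, b: 2.00}
    foliage:         {a: 0.012, b: 1.80}
    cones:           {a: 0.002, b: 1.50}

shrubs:
  "Salix spp.":
    stem:     {a: 0.040, b: 2.20}
    branches: {a: 0.015, b: 2.00}
    foliage:  {a: 0.008, b: 1.60}
  "Alnus spp.":
    stem:     {a: 0.045, b: 2.20}
    branches: {a: 0.015, b: 2.00}
    foliage:  {a: 0.008, b: 1.60}
  "Betula spp.":
    stem:     {a: 0.042, b: 2.20}
    branches: {a: 0.015, b: 2.00}
    foliage:  {a: 0.008, b: 1.60}
  default:
    stem:     {a: 0.042, b: 2.20}
    branches: {a: 0.015, b: 2.00}
    foliage:  {a: 0.008, b: 1.60}

seedlings:
  "Picea mariana":       {a: 0.030, b: 2.00}
  "Populus tremuloides": {a: 0.035, b: 2.00}
  "Betula neoalaskana":  {a: 0.034, b: 2.00}
  default:               {a: 0.032, b: 2.00}

cwd_density:
  hard:    0.40
  crumbly: 0.30
  soft:    0.20
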