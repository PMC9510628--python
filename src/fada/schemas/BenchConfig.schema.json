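{
 "description": "``fada bench`` parameters: the simulation benchmark grid.",
 "properties": {
  "L": {
   "default": 20,
   "minimum": 1,
   "title": "L",
   "type": "integer"
  },
  "M": {
   "default": 10,
   "minimum": 1,
   "title": "M",
   "type": "integer"
  },
  "P": {
   "default": 3,
   "minimum": 1,
   "title": "P",
   "type": "integer"
  },
  "T": {
   "default": 100,
   "minimum": 4,
   "title": "T",
   "type": "integer"
  },
  "models": {
   "default": [
    "spatial",
    "temporal",
    "temporal_delays",
    "spatiotemporal",
    "space_by_time"
   ],
   "items": {
    "type": "string"
   },
   "title": "Models",
   "type": "array"
  },
  "n_baseline_pairs": {
   "default": 100,
   "minimum": 1,
   "title": "N Baseline Pairs",
   "type": "integer"
  },
  "n_realizations": {
   "default": 20,
   "minimum": 1,
   "title": "N Realizations",
   "type": "integer"
  },
  "noise_levels": {
   "default": [
    0.0,
    0.05,
    0.15,
    0.25,
    0.35
   ],
   "items": {
    "type": "number"
   },
   "title": "Noise Levels",
   "type": "array"
  },
  "nonneg_variants": {
   "default": true,
   "title": "Nonneg Variants",
   "type": "boolean"
  },
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  }
 },
 "title": "BenchConfig",
 "type": "object"
}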