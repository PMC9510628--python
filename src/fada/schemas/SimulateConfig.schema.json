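{
 "description": "``fada simulate`` parameters.",
 "properties": {
  "K_gen": {
   "default": 8,
   "minimum": 1,
   "title": "K Gen",
   "type": "integer"
  },
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
  "P_sp": {
   "default": 3,
   "minimum": 1,
   "title": "P Sp",
   "type": "integer"
  },
  "P_tp": {
   "default": 3,
   "minimum": 1,
   "title": "P Tp",
   "type": "integer"
  },
  "T": {
   "default": 100,
   "minimum": 4,
   "title": "T",
   "type": "integer"
  },
  "duration_s": {
   "default": 1.0,
   "exclusiveMinimum": 0,
   "title": "Duration S",
   "type": "number"
  },
  "model_kind": {
   "default": "temporal_delays",
   "title": "Model Kind",
   "type": "string"
  },
  "n_realizations": {
   "default": 20,
   "minimum": 1,
   "title": "N Realizations",
   "type": "integer"
  },
  "noise_level": {
   "default": 0.0,
   "minimum": 0,
   "title": "Noise Level",
   "type": "number"
  },
  "nonneg": {
   "default": false,
   "title": "Nonneg",
   "type": "boolean"
  },
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  }
 },
 "title": "SimulateConfig",
 "type": "object"
}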