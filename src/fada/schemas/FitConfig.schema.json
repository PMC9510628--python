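{
 "description": "``fada fit`` / ``fada select`` parameters.",
 "properties": {
  "K": {
   "anyOf": [
    {
     "minimum": 1,
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "K"
  },
  "P": {
   "anyOf": [
    {
     "minimum": 1,
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "P"
  },
  "P_sp": {
   "anyOf": [
    {
     "minimum": 1,
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "P Sp"
  },
  "P_tp": {
   "anyOf": [
    {
     "minimum": 1,
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "P Tp"
  },
  "max_p": {
   "default": 8,
   "minimum": 3,
   "title": "Max P",
   "type": "integer"
  },
  "model_kind": {
   "title": "Model Kind",
   "type": "string"
  },
  "n_restarts": {
   "default": 5,
   "minimum": 1,
   "title": "N Restarts",
   "type": "integer"
  },
  "nonneg": {
   "anyOf": [
    {
     "type": "boolean"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Nonneg"
  },
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  }
 },
 "required": [
  "model_kind"
 ],
 "title": "FitConfig",
 "type": "object"
}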