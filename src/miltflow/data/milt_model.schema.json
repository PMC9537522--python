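{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/miltflow/milt_model.schema.json",
  "title": "miltflow process-model definition",
  "type": "object",
  "additionalProperties": false,
  "required": ["model_name", "version", "phases"],
  "$defs": {
    "method": {"enum": ["LLR", "LLA", "PA"]},
    "methods": {
      "type": "array",
      "items": {"$ref": "#/$defs/method"},
      "minItems": 1,
      "uniqueItems": true
    },
    "phaseId": {"type": "string", "pattern": "^P[0-9]{2}[ab]?$"},
    "moduleId": {"type": "string", "pattern": "^P[0-9]{2}[ab]?\\.M[0-9]{2}$"},
    "nodeId": {
      "anyOf": [
        {"$ref": "#/$defs/phaseId"},
        {"$ref": "#/$defs/moduleId"},
        {"enum": ["START", "END"]}
      ]
    }
  },
  "properties": {
    "model_name": {"type": "string"},
    "version": {"type": "string"},
    "phases": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["phase_id", "name", "methods"],
        "properties": {
          "phase_id": {"$ref": "#/$defs/phaseId"},
          "name": {"type": "string"},
          "methods": {"$ref": "#/$defs/methods"},
          "stage": {"enum": ["pre_operative", "intra_operative"]},
          "anytime": {"type": "boolean"},
          "ablation_only": {"type": "boolean"}
        }
      }
    },
    "modules": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["module_id", "name", "parent_phase"],
        "properties": {
          "module_id": {"$ref": "#/$defs/moduleId"},
          "name": {"type": "string"},
          "parent_phase": {"$ref": "#/$defs/phaseId"}
        }
      }
    },
    "transitions": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["source", "target"],
        "properties": {
          "source": {"$ref": "#/$defs/nodeId"},
          "target": {"$ref": "#/$defs/nodeId"},
          "level": {"enum": ["phase", "module"]},
          "arrow_class": {"enum": ["common", "ablation_only", "data_transfer"]},
          "methods": {"$ref": "#/$defs/methods"}
        }
      }
    },
    "module_precedence": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["phase", "before", "after"],
        "properties": {
          "phase": {"$ref": "#/$defs/phaseId"},
          "before": {"$ref": "#/$defs/moduleId"},
          "after": {"$ref": "#/$defs/moduleId"}
        }
      }
    },
    "imaging_possible": {
      "type": "array",
      "items": {"$ref": "#/$defs/nodeId"},
      "uniqueItems": true
    }
  }
}
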