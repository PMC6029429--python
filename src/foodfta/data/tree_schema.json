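{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Fault-tree definition document",
  "description": "Machine-readable schema for tree documents accepted by foodfta.parse_tree. Parsing enforces these constraints directly; this document is shipped for reference and external tooling.",
  "type": "object",
  "required": ["id", "events"],
  "properties": {
    "id": {"type": "string"},
    "title": {"type": "string"},
    "version": {"type": "string"},
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "weight"],
        "properties": {
          "id": {"type": "string", "pattern": "^[a-z0-9_]+$"},
          "description": {"type": "string"},
          "weight": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "subtrees": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "top_event"],
        "properties": {
          "id": {"type": "string", "pattern": "^[a-z0-9_]+$"},
          "title": {"type": "string"},
          "top_event": {"type": "string"}
        }
      }
    },
    "events": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "label", "kind", "subtree"],
        "properties": {
          "id": {"type": "string", "pattern": "^[a-z0-9_]+$"},
          "label": {"type": "string"},
          "kind": {"enum": ["basic", "intermediate", "top"]},
          "subtree": {"type": "string"},
          "citation": {"type": "string"},
          "gate": {
            "type": "object",
            "required": ["type", "inputs"],
            "properties": {
              "type": {"enum": ["and", "or"]},
              "inputs": {
                "type": "array",
                "minItems": 1,
                "items": {
                  "type": "string",
                  "description": "event id, or 'subtree:<subtree_id>' transfer reference"
                }
              },
              "overrides": {
                "type": "object",
                "additionalProperties": {"enum": ["and", "or"]}
              }
            }
          },
          "indicator": {
            "type": "object",
            "required": ["name", "units", "fail_when", "threshold"],
            "properties": {
              "name": {"type": "string"},
              "units": {"type": "string"},
              "fail_when": {"enum": ["ge", "le"]},
              "threshold": {"type": "number"},
              "population_fraction_threshold": {"type": "number", "minimum": 0, "maximum": 1}
            }
          }
        }
      }
    },
    "metadata": {"type": "object"}
  }
}
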