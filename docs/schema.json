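{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "molcanvas JSON interchange dialect",
  "description": "A document is either {\"m\": [molecule, ...]} or a bare molecule object. Writers omit keys holding their default value and emit keys in the order listed here; unknown keys are preserved on read and re-emitted after the known keys, sorted.",
  "oneOf": [
    {"$ref": "#/$defs/molecule"},
    {
      "type": "object",
      "required": ["m"],
      "properties": {
        "m": {"type": "array", "items": {"$ref": "#/$defs/molecule"}}
      }
    }
  ],
  "$defs": {
    "molecule": {
      "type": "object",
      "required": ["a"],
      "properties": {
        "n": {"type": "string", "description": "molecule name (omitted when empty)"},
        "a": {"type": "array", "items": {"$ref": "#/$defs/atom"}},
        "b": {"type": "array", "items": {"$ref": "#/$defs/bond"},
              "description": "omitted when the molecule has no bonds"}
      },
      "additionalProperties": true
    },
    "atom": {
      "type": "object",
      "required": ["x", "y"],
      "properties": {
        "x": {"type": "number"},
        "y": {"type": "number"},
        "z": {"type": "number", "default": 0},
        "l": {"type": "string", "default": "C",
              "description": "element symbol"},
        "c": {"type": "integer", "default": 0,
              "description": "formal charge"}
      },
      "additionalProperties": true
    },
    "bond": {
      "type": "object",
      "required": ["b", "e"],
      "properties": {
        "b": {"type": "integer", "minimum": 0,
              "description": "begin atom index"},
        "e": {"type": "integer", "minimum": 0,
              "description": "end atom index"},
        "o": {"type": "number", "default": 1,
              "enum": [0, 0.5, 1, 1.5, 2, 3],
              "description": "bond order; 0 = ionic/zero-order, 0.5 = half, 1.5 = resonance"},
        "s": {"type": "string", "enum": ["protruding", "recessed"],
              "description": "stereo wedge; omitted for plain bonds"}
      },
      "additionalProperties": true
    }
  }
}
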