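{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "applicationConfig",
  "description": "Application-specific configuration: the compute plugin to instantiate, image discovery patterns, result-table content, menu entries and ROI hotkeys.  imageNames, imageDirectoryPattern and imageFilenamePattern are positional parallel lists; tableColumnHeaders and tableEntryCalls likewise.",
  "type": "object",
  "required": ["applicationName", "ComputeClassFunctionCall"],
  "properties": {
    "applicationName": {"type": "string", "minLength": 1},
    "ComputeClassFunctionCall": {
      "type": "string",
      "description": "Compute plugin identifier, e.g. '@cComputeFatquant'; a leading '@' is stripped."
    },
    "saveDataFunction": {"type": "string"},
    "imageClassFunctionCall": {"type": "string"},
    "imageNames": {"type": "array", "items": {"type": "string"}},
    "imageDirectoryPattern": {
      "type": "array", "items": {"type": "string"},
      "description": "Glob pattern per channel selecting subdirectories of the dataset root ('imgSearchDir' accepted as an alias)."
    },
    "imageFilenamePattern": {
      "type": "array", "items": {"type": "string"},
      "description": "Glob pattern per channel selecting files inside the matched directories ('imgSearchName' accepted as an alias)."
    },
    "tableColumnHeaders": {"type": "array", "items": {"type": "string"}},
    "tableEntryCalls": {
      "type": "array",
      "items": {
        "type": "string",
        "pattern": "^\\s*[A-Za-z_]\\w*\\s*(\\(\\s*\\d+\\s*\\))?\\s*$",
        "description": "'name' is a property lookup; 'name(k)' a method call with 1-based integer argument."
      }
    },
    "menuEntries": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["path", "callback"],
        "properties": {
          "path": {"type": "array", "items": {"type": "string"}, "minItems": 2},
          "callback": {"type": "string"}
        }
      }
    },
    "roiHotkeys": {
      "type": "array",
      "items": {"type": "string", "minLength": 1, "maxLength": 1},
      "description": "Single-character ROI selection shortcuts; their count defines the number of ROIs per slice."
    },
    "uiVisibility": {
      "type": "object",
      "additionalProperties": {"enum": ["on", "off"]}
    },
    "configVersion": {"type": "string"}
  },
  "additionalProperties": true
}
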