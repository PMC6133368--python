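{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "frameworkConfig",
  "description": "General program parameters: auto-save interval, UI element visibility, selected event callbacks and keyboard shortcuts.",
  "type": "object",
  "properties": {
    "autoSaveIntervalS": {
      "type": "number",
      "exclusiveMinimum": 0,
      "description": "Auto-save interval in seconds; the host calls the auto-save hook on its own timer."
    },
    "uiVisibility": {
      "type": "object",
      "description": "UI element name ('image', 'graph', 'table', 'textbox') to 'on'/'off'.",
      "additionalProperties": {"enum": ["on", "off"]}
    },
    "selectedCallbacks": {
      "type": "object",
      "description": "Event name to handler identifier; event names must be ones the controller recognizes.",
      "propertyNames": {
        "enum": ["image_button_down", "image_button_motion", "image_button_up",
                 "graph_button_down", "mouse_wheel", "key_press", "key_release",
                 "table_cell_select", "table_cell_edit", "menu_click"]
      },
      "additionalProperties": {"type": "string"}
    },
    "keyShortcuts": {
      "type": "object",
      "description": "Key character to action name.",
      "additionalProperties": {"type": "string"}
    },
    "configVersion": {"type": "string"}
  },
  "additionalProperties": true
}
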