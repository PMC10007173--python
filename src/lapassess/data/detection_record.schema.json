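{
  "$defs": {
    "_DetectionModel": {
      "additionalProperties": false,
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "score": {
          "maximum": 1,
          "minimum": 0,
          "title": "Score",
          "type": "number"
        },
        "bbox": {
          "maxItems": 4,
          "minItems": 4,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            },
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Bbox",
          "type": "array"
        }
      },
      "required": [
        "label",
        "score",
        "bbox"
      ],
      "title": "_DetectionModel",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "camera": {
      "title": "Camera",
      "type": "string"
    },
    "frame_index": {
      "minimum": 0,
      "title": "Frame Index",
      "type": "integer"
    },
    "timestamp": {
      "title": "Timestamp",
      "type": "number"
    },
    "detections": {
      "default": [],
      "items": {
        "$ref": "#/$defs/_DetectionModel"
      },
      "title": "Detections",
      "type": "array"
    }
  },
  "required": [
    "camera",
    "frame_index",
    "timestamp"
  ],
  "title": "DetectionRecord",
  "type": "object",
  "description": "One camera frame of detections: JSON Lines streams carry one such object per line."
}
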