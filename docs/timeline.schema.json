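{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PolicyTimeline",
  "type": "object",
  "required": [
    "events"
  ],
  "properties": {
    "events": {
      "type": "array",
      "items": {
        "$defs": {
          "AvailabilityScope": {
            "enum": [
              "daily_hours",
              "specific_days_or_night",
              "outlet_type",
              "production_licensing",
              "none"
            ],
            "title": "AvailabilityScope",
            "type": "string"
          },
          "Direction": {
            "enum": [
              "restrictive",
              "liberalizing",
              "neutral"
            ],
            "title": "Direction",
            "type": "string"
          },
          "Domain": {
            "enum": [
              "taxation_price",
              "availability",
              "marketing_advertising",
              "drink_driving",
              "other"
            ],
            "title": "Domain",
            "type": "string"
          },
          "Immediacy": {
            "enum": [
              "immediate",
              "delayed"
            ],
            "title": "Immediacy",
            "type": "string"
          },
          "PolicyMeasure": {
            "description": "One typed measure within a policy event.",
            "properties": {
              "domain": {
                "$ref": "#/$defs/Domain"
              },
              "direction": {
                "$ref": "#/$defs/Direction"
              },
              "population": {
                "$ref": "#/$defs/Population"
              },
              "specific_group": {
                "default": "",
                "title": "Specific Group",
                "type": "string"
              },
              "availability_scope": {
                "$ref": "#/$defs/AvailabilityScope",
                "default": "none"
              },
              "immediacy": {
                "$ref": "#/$defs/Immediacy",
                "default": "immediate"
              },
              "description": {
                "default": "",
                "title": "Description",
                "type": "string"
              }
            },
            "required": [
              "domain",
              "direction",
              "population"
            ],
            "title": "PolicyMeasure",
            "type": "object"
          },
          "Population": {
            "enum": [
              "general",
              "specific"
            ],
            "title": "Population",
            "type": "string"
          }
        },
        "description": "All measures enacted on one date.",
        "properties": {
          "event_id": {
            "minLength": 1,
            "title": "Event Id",
            "type": "string"
          },
          "enactment_date": {
            "format": "date",
            "title": "Enactment Date",
            "type": "string"
          },
          "measures": {
            "items": {
              "$ref": "#/$defs/PolicyMeasure"
            },
            "minItems": 1,
            "title": "Measures",
            "type": "array"
          },
          "notes": {
            "default": "",
            "title": "Notes",
            "type": "string"
          }
        },
        "required": [
          "event_id",
          "enactment_date",
          "measures"
        ],
        "title": "PolicyEvent",
        "type": "object"
      }
    }
  }
}
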