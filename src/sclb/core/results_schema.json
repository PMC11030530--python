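{
 "$defs": {
  "Components": {
   "properties": {
    "datasets": {
     "items": {
      "type": "string"
     },
     "title": "Datasets",
     "type": "array"
    },
    "methods": {
     "items": {
      "$ref": "#/$defs/MethodEntry"
     },
     "title": "Methods",
     "type": "array"
    },
    "metrics": {
     "items": {
      "$ref": "#/$defs/MetricEntry"
     },
     "title": "Metrics",
     "type": "array"
    }
   },
   "required": [
    "datasets",
    "methods",
    "metrics"
   ],
   "title": "Components",
   "type": "object"
  },
  "MethodEntry": {
   "properties": {
    "name": {
     "title": "Name",
     "type": "string"
    },
    "role": {
     "title": "Role",
     "type": "string"
    }
   },
   "required": [
    "name",
    "role"
   ],
   "title": "MethodEntry",
   "type": "object"
  },
  "MetricEntry": {
   "properties": {
    "name": {
     "title": "Name",
     "type": "string"
    },
    "orientation": {
     "title": "Orientation",
     "type": "string"
    }
   },
   "required": [
    "name",
    "orientation"
   ],
   "title": "MetricEntry",
   "type": "object"
  },
  "ResourceRecord": {
   "properties": {
    "dataset": {
     "title": "Dataset",
     "type": "string"
    },
    "method": {
     "title": "Method",
     "type": "string"
    },
    "runtime_s": {
     "title": "Runtime S",
     "type": "number"
    },
    "peak_mem_bytes": {
     "title": "Peak Mem Bytes",
     "type": "integer"
    }
   },
   "required": [
    "dataset",
    "method",
    "runtime_s",
    "peak_mem_bytes"
   ],
   "title": "ResourceRecord",
   "type": "object"
  },
  "ScoreRecord": {
   "properties": {
    "dataset": {
     "title": "Dataset",
     "type": "string"
    },
    "method": {
     "title": "Method",
     "type": "string"
    },
    "metric": {
     "title": "Metric",
     "type": "string"
    },
    "value": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Value"
    }
   },
   "required": [
    "dataset",
    "method",
    "metric",
    "value"
   ],
   "title": "ScoreRecord",
   "type": "object"
  },
  "SummaryRecord": {
   "properties": {
    "dataset": {
     "title": "Dataset",
     "type": "string"
    },
    "method": {
     "title": "Method",
     "type": "string"
    },
    "overall": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Overall"
    },
    "rank": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "title": "Rank"
    }
   },
   "required": [
    "dataset",
    "method",
    "overall",
    "rank"
   ],
   "title": "SummaryRecord",
   "type": "object"
  }
 },
 "properties": {
  "schema_version": {
   "title": "Schema Version",
   "type": "string"
  },
  "task": {
   "title": "Task",
   "type": "string"
  },
  "seed": {
   "anyOf": [
    {
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "title": "Seed"
  },
  "timestamp": {
   "title": "Timestamp",
   "type": "string"
  },
  "components": {
   "$ref": "#/$defs/Components"
  },
  "raw": {
   "items": {
    "$ref": "#/$defs/ScoreRecord"
   },
   "title": "Raw",
   "type": "array"
  },
  "normalized": {
   "items": {
    "$ref": "#/$defs/ScoreRecord"
   },
   "title": "Normalized",
   "type": "array"
  },
  "summary": {
   "items": {
    "$ref": "#/$defs/SummaryRecord"
   },
   "title": "Summary",
   "type": "array"
  },
  "resources": {
   "items": {
    "$ref": "#/$defs/ResourceRecord"
   },
   "title": "Resources",
   "type": "array"
  }
 },
 "required": [
  "schema_version",
  "task",
  "seed",
  "timestamp",
  "components",
  "raw",
  "normalized",
  "summary",
  "resources"
 ],
 "title": "ResultsDocument",
 "type": "object"
}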