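{
 "$defs": {
  "ColorConfig": {
   "additionalProperties": false,
   "properties": {
    "vmax": {
     "anyOf": [
      {
       "exclusiveMinimum": 0,
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Vmax"
    },
    "palette": {
     "default": "RdBu_r",
     "title": "Palette",
     "type": "string"
    },
    "na_color": {
     "default": "#bfbfbf",
     "title": "Na Color",
     "type": "string"
    }
   },
   "title": "ColorConfig",
   "type": "object"
  },
  "ColumnMapConfig": {
   "additionalProperties": false,
   "properties": {
    "id": {
     "default": "id",
     "title": "Id",
     "type": "string"
    },
    "estimate": {
     "default": "estimate",
     "title": "Estimate",
     "type": "string"
    },
    "se": {
     "default": "se",
     "title": "Se",
     "type": "string"
    },
    "p": {
     "default": "p",
     "title": "P",
     "type": "string"
    },
    "neglogp": {
     "default": "neglogp",
     "title": "Neglogp",
     "type": "string"
    }
   },
   "title": "ColumnMapConfig",
   "type": "object"
  },
  "SizeConfig": {
   "additionalProperties": false,
   "properties": {
    "cap": {
     "anyOf": [
      {
       "exclusiveMinimum": 0,
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Cap"
    },
    "rmin": {
     "default": 0.08,
     "exclusiveMinimum": 0,
     "title": "Rmin",
     "type": "number"
    },
    "rmax": {
     "default": 0.42,
     "exclusiveMinimum": 0,
     "title": "Rmax",
     "type": "number"
    },
    "transform": {
     "default": "area",
     "title": "Transform",
     "type": "string"
    }
   },
   "title": "SizeConfig",
   "type": "object"
  },
  "StyleConfig": {
   "additionalProperties": false,
   "properties": {
    "pitch": {
     "default": 1.0,
     "exclusiveMinimum": 0,
     "title": "Pitch",
     "type": "number"
    },
    "font_size": {
     "default": 0.34,
     "exclusiveMinimum": 0,
     "title": "Font Size",
     "type": "number"
    },
    "title_size": {
     "default": 0.42,
     "exclusiveMinimum": 0,
     "title": "Title Size",
     "type": "number"
    },
    "label_rotation": {
     "default": 60.0,
     "title": "Label Rotation",
     "type": "number"
    },
    "max_label_chars": {
     "default": 22,
     "minimum": 4,
     "title": "Max Label Chars",
     "type": "integer"
    },
    "margins": {
     "default": 0.4,
     "minimum": 0,
     "title": "Margins",
     "type": "number"
    },
    "title": {
     "default": "",
     "title": "Title",
     "type": "string"
    },
    "footnote": {
     "default": "",
     "title": "Footnote",
     "type": "string"
    },
    "missing_dot": {
     "default": false,
     "title": "Missing Dot",
     "type": "boolean"
    },
    "unit_px": {
     "default": 22.0,
     "exclusiveMinimum": 0,
     "title": "Unit Px",
     "type": "number"
    },
    "background": {
     "default": "#ffffff",
     "title": "Background",
     "type": "string"
    }
   },
   "title": "StyleConfig",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "Everything one figure run needs; see the CLI for flag equivalents.",
 "properties": {
  "input": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Input"
  },
  "template": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Template"
  },
  "catalog": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Catalog"
  },
  "keyspace": {
   "default": "nh_name",
   "title": "Keyspace",
   "type": "string"
  },
  "keymap": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Keymap"
  },
  "columns": {
   "$ref": "#/$defs/ColumnMapConfig",
   "default": {
    "id": "id",
    "estimate": "estimate",
    "se": "se",
    "p": "p",
    "neglogp": "neglogp"
   }
  },
  "color": {
   "$ref": "#/$defs/ColorConfig",
   "default": {
    "vmax": null,
    "palette": "RdBu_r",
    "na_color": "#bfbfbf"
   }
  },
  "size": {
   "$ref": "#/$defs/SizeConfig",
   "default": {
    "cap": null,
    "rmin": 0.08,
    "rmax": 0.42,
    "transform": "area"
   }
  },
  "style": {
   "$ref": "#/$defs/StyleConfig",
   "default": {
    "pitch": 1.0,
    "font_size": 0.34,
    "title_size": 0.42,
    "label_rotation": 60.0,
    "max_label_chars": 22,
    "margins": 0.4,
    "title": "",
    "footnote": "",
    "missing_dot": false,
    "unit_px": 22.0,
    "background": "#ffffff"
   }
  },
  "output": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Output"
  },
  "format": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Format"
  },
  "dpi": {
   "default": 96,
   "exclusiveMinimum": 0,
   "title": "Dpi",
   "type": "integer"
  },
  "report": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Report"
  }
 },
 "title": "RunConfig",
 "type": "object"
}
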