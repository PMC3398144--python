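{
  "$comment": "Descriptive schema for locus configuration files consumed by paralogmlpa.locus_model.load_locus_map. Validation is performed by the loader itself, which raises LocusConfigError naming the offending field.",
  "type": "object",
  "required": ["geometry", "probe_sites", "psv_catalog"],
  "properties": {
    "name": {"type": "string"},
    "geometry": {
      "type": "object",
      "required": ["exon_spans", "pseudogene_exons"],
      "properties": {
        "exon_spans": {
          "type": "object",
          "description": "exon label -> [coding start, coding end] (inclusive)",
          "additionalProperties": {
            "type": "array",
            "items": {"type": "integer"},
            "minItems": 2,
            "maxItems": 2
          }
        },
        "pseudogene_exons": {
          "type": "array",
          "description": "site groups structurally present at the pseudogene locus",
          "items": {"type": "string"}
        },
        "exon10_span_kb": {"type": "number"},
        "duplicon_inverted": {"type": "boolean"},
        "interduplicon_distance_mb": {"type": "number"}
      }
    },
    "probe_sites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "exon_label", "specificity"],
        "properties": {
          "id": {"type": "string"},
          "exon_label": {"type": "string"},
          "specificity": {
            "enum": ["gene", "pseudogene", "universal", "reference"]
          },
          "ligation_pos": {
            "type": "string",
            "description": "HGVS c. position; required unless specificity=reference"
          }
        }
      }
    },
    "psv_catalog": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "id", "position", "gene_allele", "pseudogene_allele",
          "kind", "gene_context_consequence"
        ],
        "properties": {
          "id": {"type": "string"},
          "position": {"type": "string"},
          "gene_allele": {"type": "string"},
          "pseudogene_allele": {"type": "string"},
          "kind": {
            "enum": ["substitution", "insertion", "deletion", "duplication"]
          },
          "gene_context_consequence": {
            "enum": ["synonymous", "missense", "frameshift", "utr", "intronic"]
          }
        }
      }
    },
    "asp_assay": {
      "type": "object",
      "required": [
        "forward", "reverse", "product_length_bp",
        "control_region", "control_product_length_bp"
      ],
      "properties": {
        "forward": {
          "type": "object",
          "required": ["position", "origin"],
          "properties": {
            "position": {"type": "string"},
            "origin": {"enum": ["gene", "pseudogene"]}
          }
        },
        "reverse": {
          "type": "object",
          "required": ["position", "origin"],
          "properties": {
            "position": {"type": "string"},
            "origin": {"enum": ["gene", "pseudogene"]}
          }
        },
        "product_length_bp": {"type": "integer"},
        "control_region": {"type": "string"},
        "control_product_length_bp": {"type": "integer"}
      }
    }
  }
}
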