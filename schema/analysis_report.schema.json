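{
 "$defs": {
  "ComparisonRow": {
   "properties": {
    "structure_a": {
     "title": "Structure A",
     "type": "string"
    },
    "structure_b": {
     "title": "Structure B",
     "type": "string"
    },
    "mode": {
     "title": "Mode",
     "type": "string"
    },
    "tm_mean": {
     "title": "Tm Mean",
     "type": "number"
    },
    "rmsd_mean": {
     "title": "Rmsd Mean",
     "type": "number"
    },
    "n_pairs_mean": {
     "title": "N Pairs Mean",
     "type": "number"
    },
    "n_comparisons": {
     "title": "N Comparisons",
     "type": "integer"
    }
   },
   "required": [
    "structure_a",
    "structure_b",
    "mode",
    "tm_mean",
    "rmsd_mean",
    "n_pairs_mean",
    "n_comparisons"
   ],
   "title": "ComparisonRow",
   "type": "object"
  },
  "CrosslinkCandidateRow": {
   "properties": {
    "structure": {
     "title": "Structure",
     "type": "string"
    },
    "residue_a": {
     "items": {},
     "title": "Residue A",
     "type": "array"
    },
    "residue_b": {
     "items": {},
     "title": "Residue B",
     "type": "array"
    },
    "cb_cb_A": {
     "title": "Cb Cb A",
     "type": "number"
    },
    "ca_ca_A": {
     "title": "Ca Ca A",
     "type": "number"
    },
    "rank": {
     "title": "Rank",
     "type": "integer"
    }
   },
   "required": [
    "structure",
    "residue_a",
    "residue_b",
    "cb_cb_A",
    "ca_ca_A",
    "rank"
   ],
   "title": "CrosslinkCandidateRow",
   "type": "object"
  },
  "DistanceClassRow": {
   "properties": {
    "structure": {
     "title": "Structure",
     "type": "string"
    },
    "class_label": {
     "title": "Class Label",
     "type": "string"
    },
    "members": {
     "title": "Members",
     "type": "integer"
    },
    "mean_A": {
     "title": "Mean A",
     "type": "number"
    },
    "rmsd_A": {
     "title": "Rmsd A",
     "type": "number"
    }
   },
   "required": [
    "structure",
    "class_label",
    "members",
    "mean_A",
    "rmsd_A"
   ],
   "title": "DistanceClassRow",
   "type": "object"
  },
  "DisulfideRow": {
   "properties": {
    "structure": {
     "title": "Structure",
     "type": "string"
    },
    "cys_a": {
     "items": {},
     "title": "Cys A",
     "type": "array"
    },
    "cys_b": {
     "items": {},
     "title": "Cys B",
     "type": "array"
    },
    "sg_sg_A": {
     "title": "Sg Sg A",
     "type": "number"
    },
    "interchain": {
     "title": "Interchain",
     "type": "boolean"
    }
   },
   "required": [
    "structure",
    "cys_a",
    "cys_b",
    "sg_sg_A",
    "interchain"
   ],
   "title": "DisulfideRow",
   "type": "object"
  },
  "InterfaceRow": {
   "properties": {
    "structure": {
     "title": "Structure",
     "type": "string"
    },
    "pair_label": {
     "title": "Pair Label",
     "type": "string"
    },
    "n_equivalent": {
     "title": "N Equivalent",
     "type": "integer"
    },
    "interface_area_A2": {
     "title": "Interface Area A2",
     "type": "number"
    },
    "buried_area_total_A2": {
     "title": "Buried Area Total A2",
     "type": "number"
    },
    "n_contacts": {
     "title": "N Contacts",
     "type": "number"
    },
    "n_hbonds": {
     "title": "N Hbonds",
     "type": "number"
    }
   },
   "required": [
    "structure",
    "pair_label",
    "n_equivalent",
    "interface_area_A2",
    "buried_area_total_A2",
    "n_contacts",
    "n_hbonds"
   ],
   "title": "InterfaceRow",
   "type": "object"
  },
  "Provenance": {
   "properties": {
    "package_version": {
     "title": "Package Version",
     "type": "string"
    },
    "seed": {
     "title": "Seed",
     "type": "integer"
    },
    "order": {
     "title": "Order",
     "type": "integer"
    },
    "atom_mode": {
     "title": "Atom Mode",
     "type": "string"
    },
    "contact_cutoff": {
     "title": "Contact Cutoff",
     "type": "number"
    },
    "cb_window": {
     "items": {
      "type": "number"
     },
     "title": "Cb Window",
     "type": "array"
    },
    "sasa_probe_radius": {
     "title": "Sasa Probe Radius",
     "type": "number"
    },
    "sasa_sphere_points": {
     "title": "Sasa Sphere Points",
     "type": "integer"
    },
    "inputs": {
     "items": {
      "type": "string"
     },
     "title": "Inputs",
     "type": "array"
    },
    "timestamp": {
     "description": "UTC, excluded from determinism checks",
     "title": "Timestamp",
     "type": "string"
    }
   },
   "required": [
    "package_version",
    "seed",
    "order",
    "atom_mode",
    "contact_cutoff",
    "cb_window",
    "sasa_probe_radius",
    "sasa_sphere_points",
    "inputs",
    "timestamp"
   ],
   "title": "Provenance",
   "type": "object"
  }
 },
 "description": "Machine-readable result of a full pipeline run.",
 "properties": {
  "distance_classes": {
   "items": {
    "$ref": "#/$defs/DistanceClassRow"
   },
   "title": "Distance Classes",
   "type": "array"
  },
  "comparisons": {
   "items": {
    "$ref": "#/$defs/ComparisonRow"
   },
   "title": "Comparisons",
   "type": "array"
  },
  "interfaces": {
   "items": {
    "$ref": "#/$defs/InterfaceRow"
   },
   "title": "Interfaces",
   "type": "array"
  },
  "crosslink_candidates": {
   "items": {
    "$ref": "#/$defs/CrosslinkCandidateRow"
   },
   "title": "Crosslink Candidates",
   "type": "array"
  },
  "disulfides": {
   "items": {
    "$ref": "#/$defs/DisulfideRow"
   },
   "title": "Disulfides",
   "type": "array"
  },
  "crosslink_consistency": {
   "additionalProperties": true,
   "title": "Crosslink Consistency",
   "type": "object"
  },
  "provenance": {
   "$ref": "#/$defs/Provenance"
  }
 },
 "required": [
  "distance_classes",
  "comparisons",
  "interfaces",
  "crosslink_candidates",
  "disulfides",
  "crosslink_consistency",
  "provenance"
 ],
 "title": "AnalysisReport",
 "type": "object"
}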