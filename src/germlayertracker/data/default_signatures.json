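{
  "panel": "GermLayerTracker",
  "version": "1.0",
  "signatures": [
    {
      "name": "PSC",
      "target_class": "PSC",
      "markers": [
        {"probe_id": "cg00661673", "orientation": "hypo"},
        {"probe_id": "cg00933813", "orientation": "hypo"},
        {"probe_id": "cg21699252", "orientation": "hypo"}
      ],
      "metadata": {
        "genes": {"cg00661673": "PALLD", "cg00933813": null, "cg21699252": "MYCNOS"},
        "orientation_verified": true,
        "orientation_source": "published: all three pluripotency CpGs are hypomethylated in pluripotent cells"
      }
    },
    {
      "name": "ENDO",
      "target_class": "ENDO",
      "markers": [
        {"probe_id": "cg20548013", "orientation": "hyper"},
        {"probe_id": "cg14521421", "orientation": "hyper"},
        {"probe_id": "cg08913523", "orientation": "hyper"}
      ],
      "metadata": {
        "genes": {"cg20548013": "PHACTR1", "cg14521421": "DENND2B", "cg08913523": null},
        "orientation_verified": false,
        "orientation_source": "default 'hyper' placeholder; per-CpG directions are not published — re-derive with orient_signature() on a labeled reference dataset before scoring"
      }
    },
    {
      "name": "MESO",
      "target_class": "MESO",
      "markers": [
        {"probe_id": "cg14708360", "orientation": "hyper"},
        {"probe_id": "cg08826152", "orientation": "hyper"},
        {"probe_id": "cg11599718", "orientation": "hyper"}
      ],
      "metadata": {
        "genes": {"cg14708360": null, "cg08826152": "ADORA2B", "cg11599718": "VPS37B"},
        "orientation_verified": false,
        "orientation_source": "default 'hyper' placeholder; per-CpG directions are not published — re-derive with orient_signature() on a labeled reference dataset before scoring"
      }
    },
    {
      "name": "ECTO",
      "target_class": "ECTO",
      "markers": [
        {"probe_id": "cg01907071", "orientation": "hyper"},
        {"probe_id": "cg18118164", "orientation": "hyper"},
        {"probe_id": "cg13075942", "orientation": "hyper"}
      ],
      "metadata": {
        "genes": {"cg01907071": "THSD4", "cg18118164": "EFNA5", "cg13075942": "RAD51B"},
        "orientation_verified": false,
        "orientation_source": "default 'hyper' placeholder; per-CpG directions are not published — re-derive with orient_signature() on a labeled reference dataset before scoring"
      }
    },
    {
      "name": "ENDOMESO",
      "target_class": "ENDOMESO",
      "markers": [
        {"probe_id": "cg23385847", "orientation": "hyper"},
        {"probe_id": "cg24919344", "orientation": "hyper"},
        {"probe_id": "cg11147278", "orientation": "hyper"}
      ],
      "metadata": {
        "genes": {"cg23385847": "CAMK4", "cg24919344": null, "cg11147278": null},
        "orientation_verified": false,
        "orientation_source": "default 'hyper' placeholder; per-CpG directions are not published — re-derive with orient_signature() on a labeled reference dataset before scoring"
      }
    }
  ]
}
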