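{
  "description": "Catalogue of the Rhodnius prolixus A1 aspartic-protease gene family after proteogenomic curation: final gene entities, the input gene IDs each consolidates, genomic locations, digestive-transcript and UniProt protein accessions, protein masses (Da), expression-evidence class, and the correction class applied (null = annotation unchanged). Transcribed from the published gene table; the transcript-only call for R4G2R0 is inferred from the accompanying case narrative and flagged in notes.",
  "entities": [
    {
      "final_id": "RPRC015079",
      "input_gene_ids": ["RPRC015079"],
      "location": "KQ035270:22,283-29,217",
      "transcript_ids": ["Rp-6850"],
      "protein_ids": ["R4G5J4"],
      "mass_da": [43622],
      "status": "gene",
      "evidence": "protein",
      "correction_class": null,
      "notes": ""
    },
    {
      "final_id": "RPRC015076",
      "input_gene_ids": ["RPRC015076"],
      "location": "KQ035270:31,145-38,451",
      "transcript_ids": ["Rp-6846"],
      "protein_ids": ["T1IFK7", "R4G5J6"],
      "mass_da": [43383, 44846],
      "status": "gene",
      "evidence": "protein",
      "correction_class": "intron_retention",
      "notes": "two proteoforms; the longer arises by in-frame intron retention (7 extra residues)"
    },
    {
      "final_id": "RPRC006028-RPRC006290",
      "input_gene_ids": ["RPRC006028", "RPRC006290"],
      "location": "KQ034219:483,622-531,975",
      "transcript_ids": ["Rp-1760"],
      "protein_ids": ["R4G4V2"],
      "mass_da": [42388],
      "status": "gene",
      "evidence": "protein",
      "correction_class": "merge",
      "notes": "novel intergenic exon (525,409-525,501); single-exon fragment re-stranded to plus; 9-exon gene"
    },
    {
      "final_id": "RPRC006759",
      "input_gene_ids": ["RPRC006759"],
      "location": "KQ034118:1,424,212-1,434,669",
      "transcript_ids": ["RP-3415"],
      "protein_ids": ["R4FJC3"],
      "mass_da": [45508],
      "status": "gene",
      "evidence": "protein",
      "correction_class": "terminal_exon_addition",
      "notes": "novel C-terminal exon with stop (1,424,212-1,424,370); former ninth exon reclassified as intron"
    },
    {
      "final_id": "RPRC004330-RPRC010954",
      "input_gene_ids": ["RPRC004330", "RPRC010954"],
      "location": "KQ03421:413,307-428,406",
      "transcript_ids": ["RP-7417"],
      "protein_ids": ["R4FKP9"],
      "mass_da": [43820],
      "status": "gene",
      "evidence": "protein",
      "correction_class": "cross_contig_patch",
      "notes": "missing terminal-exon fragment recovered on ACPB03042655 (668-786); shared peptide bridges both pieces"
    },
    {
      "final_id": "RPRC002478-RPRC002479",
      "input_gene_ids": ["RPRC002478", "RPRC002479"],
      "location": "KQ035965:948-11,511",
      "transcript_ids": ["Rp-10596"],
      "protein_ids": ["R4G3V2"],
      "mass_da": [44082],
      "status": "gene",
      "evidence": "protein",
      "correction_class": "merge",
      "notes": "adjacent truncated fragments; unannotated internal exon (7269-8151); C-terminal exon on KQ034470 (433,885-434,037)"
    },
    {
      "final_id": "RPRC014747-RPRC012504-RPRC008989",
      "input_gene_ids": ["RPRC014747", "RPRC012504", "RPRC008989"],
      "location": "KQ037387:3342-4462 / KQ036163:11,128-17,438",
      "transcript_ids": ["Rp-2814"],
      "protein_ids": ["R4FNG1"],
      "mass_da": [43137],
      "status": "gene",
      "evidence": "protein",
      "correction_class": "merge",
      "notes": "three-way consolidation across two contigs"
    },
    {
      "final_id": "RPRC012508-RPRC012513",
      "input_gene_ids": ["RPRC012508", "RPRC012513"],
      "location": "KQ036163:1315-9223",
      "transcript_ids": ["RP-8066"],
      "protein_ids": ["R4G4V0"],
      "mass_da": [43233],
      "status": "gene",
      "evidence": "transcript",
      "correction_class": "inversion_fix",
      "notes": "inverted block (3479-6718) re-oriented; three new exons (1315-4580) on the negative strand; not identified by proteomics"
    },
    {
      "final_id": "RPRC004171",
      "input_gene_ids": ["RPRC004171"],
      "location": "KQ034610:35,399-39,782",
      "transcript_ids": ["RP-6421"],
      "protein_ids": ["R4G2R0"],
      "mass_da": [45341],
      "status": "gene",
      "evidence": "transcript",
      "correction_class": "upstream_exon_addition",
      "notes": "two upstream exons recovered from the transcript; 8-exon gene; transcript-only call inferred from the case narrative"
    },
    {
      "final_id": "RPRC012785",
      "input_gene_ids": ["RPRC012785"],
      "location": "KQ034079:4811-10,271",
      "transcript_ids": ["Rp-2217"],
      "protein_ids": ["R4FNN7"],
      "mass_da": [44222],
      "status": "gene",
      "evidence": "protein",
      "correction_class": null,
      "notes": ""
    },
    {
      "final_id": "RPRC015082",
      "input_gene_ids": ["RPRC015082"],
      "location": "KQ035270:12,987-20,613",
      "transcript_ids": ["RP-82226"],
      "protein_ids": ["R4FP52"],
      "mass_da": [43408],
      "status": "gene",
      "evidence": "protein",
      "correction_class": null,
      "notes": ""
    },
    {
      "final_id": "RPRC006698",
      "input_gene_ids": ["RPRC006698"],
      "location": "KQ034534:71,381-77,412",
      "transcript_ids": ["RP-5007"],
      "protein_ids": ["R4FMP1"],
      "mass_da": [43907],
      "status": "gene",
      "evidence": "protein",
      "correction_class": null,
      "notes": ""
    },
    {
      "final_id": "RPRC012786",
      "input_gene_ids": ["RPRC012786"],
      "location": "KQ034079:13,511-18,584",
      "transcript_ids": [],
      "protein_ids": ["T1I914"],
      "mass_da": [42923],
      "status": "gene",
      "evidence": "protein",
      "correction_class": null,
      "notes": ""
    },
    {
      "final_id": "RPRC012664",
      "input_gene_ids": ["RPRC012664"],
      "location": "KQ035425:10,005-15,720",
      "transcript_ids": [],
      "protein_ids": ["T1I8P2"],
      "mass_da": [35511],
      "status": "gene",
      "evidence": "none",
      "correction_class": null,
      "notes": "missing N-terminal; no expression evidence"
    },
    {
      "final_id": "RPRC002696",
      "input_gene_ids": ["RPRC002696"],
      "location": "KQ034126:569,709-570,120",
      "transcript_ids": [],
      "protein_ids": ["T1HF74"],
      "mass_da": [11732],
      "status": "gene",
      "evidence": "none",
      "correction_class": null,
      "notes": "truncated; no expression evidence"
    },
    {
      "final_id": "RPRC011752",
      "input_gene_ids": ["RPRC011752"],
      "location": "ACPB03043556:28-700",
      "transcript_ids": [],
      "protein_ids": ["T1I633"],
      "mass_da": [15897],
      "status": "putative_fragment",
      "evidence": "none",
      "correction_class": null,
      "notes": "truncated; likely a fragment of another gene; not a confident individual gene"
    },
    {
      "final_id": "RPRC012487",
      "input_gene_ids": ["RPRC012487"],
      "location": "ACPB03042715:162-362",
      "transcript_ids": [],
      "protein_ids": ["T1I865"],
      "mass_da": [7486],
      "status": "putative_fragment",
      "evidence": "none",
      "correction_class": null,
      "notes": "truncated; likely a fragment of another gene; not a confident individual gene"
    }
  ]
}
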