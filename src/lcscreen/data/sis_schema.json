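{
  "version": "1.0",
  "comment": "Column order for each assessment-bundle table. The upstream exchange format does not publish a frozen schema, so columns are configuration, not code: edit here to track schema drift.",
  "tables": {
    "allfields": ["internal_taxon_id", "eoo_km2", "aoo_km2", "record_count", "tdwg_count", "ecological_system", "bibliography"],
    "assessments": ["internal_taxon_id", "redlist_category", "redlist_criteria", "rationale", "population_trend", "assessment_date", "language"],
    "countries": ["internal_taxon_id", "country", "wgsrpd_l3_code", "presence", "origin", "seasonality"],
    "credits": ["internal_taxon_id", "credit_type", "name", "order"],
    "habitats": ["internal_taxon_id", "habitat_code", "habitat_name", "suitability", "season", "major_importance"],
    "plantspecific": ["internal_taxon_id", "growth_form"],
    "taxonomy": ["internal_taxon_id", "family", "genus", "species", "taxonomic_authority"]
  },
  "points": ["internal_taxon_id", "binomial", "dec_long", "dec_lat", "presence", "origin", "seasonal", "source_id"]
}
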