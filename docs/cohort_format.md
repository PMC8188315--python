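# Cohort bundle format (`graphonc-cohort/1`)

A cohort is one JSON document holding every patient's bundle plus the cancer
labels.  The layout mirrors the FHIR resources the record families correspond
to (`Patient`, `Observation-genetics`, `Observation`, `Condition`,
`Medication`, `FamilyMemberHistory`), flattened to the fields the pipeline
uses.  The reader ignores unknown fields with a warning and tolerates missing
optional fields; it rejects duplicate patient ids, malformed dates and records
whose code system does not match their family.

```json
{
  "format": "graphonc-cohort/1",
  "bundles": [
    {
      "patient": {"patient_id": "P0001", "age_years": 63, "sex": "male"},
      "genetics": [
        {"gene": "EGFR", "report_date": "2020-11-02"}
      ],
      "labs": [
        {"loinc": "2160-0", "value": 1.4, "unit": "mg/dL",
         "ref_low": 0.6, "ref_high": 1.2, "effective_date": "2020-06-15"}
      ],
      "conditions": [
        {"icd9": "401.9", "recorded_date": "2019-03-01"}
      ],
      "medications": [
        {"rxnorm": "5956", "recorded_date": "2020-10-20"}
      ],
      "family_history": [
        {"icd9": "429.9"}
      ]
    }
  ],
  "labels": {
    "P0001": {"cancer": "162.9", "diagnosis_date": "2020-12-01"}
  }
}
```

Field notes:

* `sex` is one of `male` / `female` / `unknown` (default `unknown`).
* Every coded record accepts an optional `display` string; display text never
  participates in identity.
* Lab `value`, `ref_low` and `ref_high` may each be `null`.  A missing value
  makes the result *Null*; a missing bound is treated as an open bound.
* Dates are ISO-8601 calendar dates (no times; the pipeline reasons in months).
* `labels` maps patient id to exactly one of the nine ICD-9 target cancer
  codes: 153.9 (colon), 155 (liver), 157.9 (pancreas), 162.9 (bronchus/lung),
  171.9 (soft tissue), 174.9 (breast), 183 (ovary), 185 (prostate),
  193 (thyroid).  ICD-9 codes are stored verbatim as strings — `"155"` and
  `"153.9"` are both valid spellings and no decimal normalization is applied.
* Labelled patient ids must be a subset of bundle patient ids; unlabelled
  patients are allowed (they are ignored by supervised stages).
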