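# JSON model dialect

`commitgf` reads and writes metabolic models in SBML Level 3 (FBC) and in a
JSON dialect that mirrors the in-memory classes one-to-one.  The JSON form
exists so fixtures and scripts can construct models without an SBML
toolchain; SBML remains the interchange format.

A model document is a single JSON object:

```json
{
 "id": "org1",
 "metabolites": [
  {"id": "glc", "compartment": "e", "name": "D-glucose",
   "formula": "C6H12O6", "charge": 0}
 ],
 "reactions": [
  {"id": "T_glc",
   "stoichiometry": [["glc", "e", -1.0], ["glc", "c", 1.0]],
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "gpr": "(g1 and g2) or g3",
   "ec_numbers": ["2.7.1.2"],
   "kind": "transport"}
 ],
 "genes": ["g1", "g2", "g3"],
 "biomass_id": "BIO_org1"
}
```

Field notes:

- **compartment** is one of `"c"` (cytosol), `"e"` (extracellular),
  `"boundary"`.  A metabolite is identified by the pair (id, compartment).
- **stoichiometry** is a list of `[metabolite_id, compartment, coefficient]`
  triples; negative coefficients are consumed, positive produced.
- **lower_bound / upper_bound** are fluxes in mmol·gDW⁻¹·h⁻¹ (h⁻¹ for the
  biomass reaction); they default to ±1000.  Exchange reactions follow the
  convention negative flux = uptake.
- **gpr** is a boolean gene expression over gene identifiers using `and`,
  `or`, and parentheses; it may be empty.
- **kind** is one of `internal`, `transport`, `exchange`, `sink`,
  `biomass`.  When omitted it is inferred from structure: a reaction with a
  single extracellular metabolite is an exchange, a single cytosolic
  metabolite a sink, more than one compartment a transport, anything else
  internal.
- **biomass_id**, when present, must name a reaction of kind `biomass`.

Every stoichiometry entry must resolve to a declared metabolite; dangling
references are a validation error.  Round-trips through either dialect are
lossless for all fields above.
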