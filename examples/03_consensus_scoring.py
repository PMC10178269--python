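"""Score the packaged per-tool predictions with the >=60% consensus rule
and inspect one worked example: the PTPRS missense variant, damaging for
six of its seven informative predictors."""

from famseg import ConsensusConfig, classify_all, consensus_call, load_joined_fixture

records = load_joined_fixture()

ptprs = next(r for r in records if r.gene == "PTPRS")
call = consensus_call(ptprs)
print(f"PTPRS ({ptprs.variant_id}):")
for tool, verdict in call.verdicts.items():
    print(f"  {tool:<18s} {verdict}")
print(f"  -> {call.n_damaging}/{call.n_available} damaging, "
      f"candidate: {call.is_candidate}")
print()

for mode in ("available", "all_seven"):
    calls, summary = classify_all(records, ConsensusConfig(denominator=mode))
    print(f"denominator = {mode:<10s}: {summary['n_candidates']} of "
          f"{summary['n_records']} variants are consensus candidates "
          f"({summary['n_low_support']} with <3 informative tools)")

print()
print("'available' divides by the tools that returned a prediction (the "
      "permissive reading); 'all_seven' divides by all seven regardless of "
      "missingness, which penalizes truncating variants most predictors "
      "cannot score.")
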