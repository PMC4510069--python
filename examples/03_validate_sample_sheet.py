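"""Load, validate and query the packaged 94-sample sheet.

The sheet mirrors the GEO GSE51011 inventory: ChIP-seq (Myc, Pol2,
histone marks), RNA-seq, 4sU-seq and DNAseI-seq samples across four Myc
model systems, with replicate bookkeeping and input/baseline links
(including dash-truncated ranges like GSM1234734-7).
"""

from stallkit import load_packaged_sheet, query, validate_sheet
from stallkit.metadata import Severity, expand_baseline_reference

records = load_packaged_sheet()
print(f"{len(records)} samples in the sheet")

issues = validate_sheet(records)
errors = [i for i in issues if i.severity is Severity.ERROR]
print(f"validation: {len(errors)} errors, {len(issues) - len(errors)} warnings")
for issue in issues:
    print(f"  {issue}")
# the warnings are verbatim oddities of the published inventory (input
# rows that list an antibody target); every baseline link resolves.

print("\nranged baseline GSM1234734-7 expands to:",
      ", ".join(expand_baseline_reference("GSM1234734-7")))

pol2 = query(records, target="Pol2")
print(f"\n{len(pol2)} RNAPII ChIP-seq samples (the SI inputs):")
for r in pol2:
    print(f"  {r.sample_id}  {r.name:28s} {r.model:10s} genome={r.genome}")
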