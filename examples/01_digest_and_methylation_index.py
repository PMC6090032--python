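"""In-silico methylation-sensitive restriction analysis of an rDNA array.

Builds the default 43-kb repeat-unit map, digests genomes with increasing
hypermethylated content under (HpaII + Csp6I) vs (MspI + Csp6I), prints the
Southern band pattern of a hypermethylated genome, and shows how the
methylation index M rises with the hypermethylated fraction and maps back
to it exactly.
"""

from rdnacn import (
    build_default_unit,
    classify_M,
    compute_M,
    default_retention,
    digest_genome,
    estimate_hyper_fraction,
    gain,
    genome_from_hyper,
    render_southern_pattern,
)

unit = build_default_unit()
retention = default_retention(unit)

print(f"repeat unit: {unit.unit_length / 1000:.0f} kb, "
      f"coding region {unit.coding_region[0]}..{unit.coding_region[1]}")
print(f"retention midpoint l50 = {retention.l50:.0f} bp, "
      f"uncut/cut signal gain g = {gain(unit, retention):.2f}\n")

print("hypermethylated fraction -> methylation index M -> group -> inverted f")
for f in (0.00, 0.05, 0.10, 0.20, 0.30):
    m = compute_M(genome_from_hyper(400, f), unit, retention)
    f_hat, _, _ = estimate_hyper_fraction(m, retention=retention, unit=unit)
    print(f"  f = {f:.2f}   M = {m:.3f}   {classify_M(m)}   f_hat = {f_hat:.3f}")

print("\nSouthern pattern, ETS-18S probe, 30% hypermethylated genome,")
print("HpaII + Csp6I digest (top bands are merged hypermethylated fragments):")
spectra = digest_genome(unit, genome_from_hyper(400, 0.30), ("HpaII", "Csp6I"))
bands = render_southern_pattern(spectra, "p(ETS-18S)", unit)
print(bands.head(8).to_string(index=False))
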