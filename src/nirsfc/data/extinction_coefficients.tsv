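# Molar extinction coefficients of haemoglobin, units 1/(mM*cm), interpolated at the
# instrument wavelengths from the standard compilation of haemoglobin extinction spectra
# (Prahl/Cope lineage, as bundled with common NIRS analysis toolboxes).
# The analysis-side inversion and the synthetic forward model both read this one table.
wavelength_nm	e_hbo2	e_hhb
763	0.6096	1.4703
841	1.0364	0.7086
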