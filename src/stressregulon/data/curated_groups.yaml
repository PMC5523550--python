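# Curated gene groups of the RT-qPCR validation panel for the A. nidulans
# control vs ΔatfA oxidative-stress experiment.  These are the panel genes
# actually measured by qPCR; the full chip-wide AspGD-derived groups are
# supplied by the user at analysis time.
antioxidant:
  label: Antioxidant enzyme genes
  genes: [AN9339, AN10220, AN0932, AN2846, AN7567, AN5831, AN3581, AN8692]
siderophore:
  label: Siderophore biosynthesis genes
  genes: [AN5823, AN8251]
iron_sulfur:
  label: Iron-sulfur cluster assembly genes
  genes: [AN10584, AN2508, AN4655, AN0447, AN1407, AN2155, AN3632, AN5953, AN8485, AN10012, AN11060]
two_component:
  label: Two-component signal transduction system genes
  genes: [AN5296, AN1800, AN3101, AN7945, AN4113, AN6820, AN2363]
nitrate:
  label: Nitrate utilization cluster (niaD, niiA, crnA)
  genes: [AN1006, AN1007, AN1008]
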