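# Wavenumber -> biomolecule assignments for 785 nm live-cell SERS spectra.
# In-text literature subset; extensible. Every entry carries a citation tag.
entries:
  - {center: 645.0, molecule: "[Fe-S] cluster", group: other, note: "mitochondrial electron transfer chain", source: "lit:fe-s-raman"}
  - {center: 670.0, molecule: nucleotide, group: DNA, note: "DNA nucleotide bond vibration", source: "lit:dna-raman"}
  - {center: 692.0, molecule: nucleotide, group: DNA, note: "DNA nucleotide bond vibration", source: "lit:dna-raman"}
  - {center: 720.0, molecule: adenine, group: DNA, note: "adenine in DNA; shared with phospholipids", source: "lit:dna-raman"}
  - {center: 720.0, molecule: phospholipid, group: lipid, note: "phospholipid line coincident with adenine", source: "lit:lipid-raman"}
  - {center: 790.0, molecule: cytosine, group: DNA, note: "most intensive cytosine line in DNA", source: "lit:dna-raman"}
  - {center: 802.0, molecule: nucleotide, group: DNA, note: "DNA nucleotide bond vibration", source: "lit:dna-raman"}
  - {center: 1330.0, molecule: nucleotide, group: DNA, note: "DNA nucleotide bond vibration", source: "lit:dna-raman"}
  - {lo: 745.0, hi: 760.0, molecule: heme, group: heme, note: "hemes in mitochondrial cytochromes", source: "lit:heme-raman"}
  - {center: 750.0, molecule: heme C, group: heme, note: "more specific to heme C", source: "lit:cytochrome-raman"}
  - {center: 760.0, molecule: heme B, group: heme, note: "more specific to heme B", source: "lit:cytochrome-raman"}
  - {center: 1206.0, molecule: heme, group: heme, note: "heme line of mitochondrial cytochromes", source: "lit:heme-raman"}
  - {center: 775.0, molecule: RNA, group: RNA, note: "RNA nucleotide bond vibration", source: "lit:rna-raman"}
  - {center: 812.0, molecule: RNA, group: RNA, note: "intensive RNA line", source: "lit:rna-raman"}
  - {center: 822.0, molecule: RNA, group: RNA, note: "RNA nucleotide bond vibration", source: "lit:rna-raman"}
  - {center: 833.0, molecule: RNA, group: RNA, note: "RNA nucleotide bond vibration", source: "lit:rna-raman"}
  - {center: 1510.0, molecule: RNA, group: RNA, note: "intensive RNA line", source: "lit:rna-raman"}
  - {center: 1000.0, molecule: phenylalanine, group: protein, note: "protein ring-breathing line", source: "lit:protein-raman"}
  - {center: 1141.0, molecule: protein, group: protein, note: "protein line", source: "lit:protein-raman"}
  - {center: 1180.0, molecule: protein, group: protein, note: "intensive protein line", source: "lit:protein-raman"}
  - {center: 1200.0, molecule: protein, group: protein, note: "protein line", source: "lit:protein-raman"}
  - {center: 1225.0, molecule: protein, group: protein, note: "protein line", source: "lit:protein-raman"}
  - {center: 1350.0, molecule: protein, group: protein, note: "protein/lipid region line", source: "lit:protein-raman"}
  - {lo: 1360.0, hi: 1370.0, molecule: protein, group: protein, note: "protein window", source: "lit:protein-raman"}
  - {center: 1570.0, molecule: protein, group: protein, note: "intensive protein line", source: "lit:protein-raman"}
  - {center: 1078.0, molecule: lipid, group: lipid, note: "alkyl C-C gauche stretch in lipids", source: "lit:lipid-raman"}
  - {lo: 1260.0, hi: 1280.0, molecule: lipid, group: lipid, note: "lipid window (nuclear membrane region)", source: "lit:lipid-raman"}
  - {center: 1270.0, molecule: unsaturated fatty acids, group: lipid, note: "unsaturated fatty acid line", source: "lit:lipid-raman"}
  - {center: 1445.0, molecule: lipid, group: lipid, note: "most intensive lipid line (CH2 bend)", source: "lit:lipid-raman"}
  - {center: 1446.0, molecule: lipid, group: lipid, note: "CH2 bend, lipids and proteins", source: "lit:lipid-raman"}
  - {center: 912.0, molecule: carbohydrate, group: carbohydrate, note: "carbohydrate line", source: "lit:carb-raman"}
  - {center: 1120.0, molecule: glycoprotein, group: carbohydrate, note: "carbohydrate line of glycoproteins", source: "lit:carb-raman"}
  - {center: 1010.0, molecule: substrate, group: substrate, note: "nanostructure/substrate line outside cells", source: "lit:substrate"}
  - {center: 1065.0, molecule: substrate, group: substrate, note: "nanostructure/substrate line outside cells", source: "lit:substrate"}
  - {center: 1203.0, molecule: substrate, group: substrate, note: "nanostructure/substrate line outside cells", source: "lit:substrate"}
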