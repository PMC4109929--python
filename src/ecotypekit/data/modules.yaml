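# Default metabolic-module definitions: methylotrophy and nitrogen
# metabolism modules for methylotrophic betaproteobacteria.
#
# Schema per entry:
#   module_id:            row label in the inventory matrix
#   gene_symbols:         required symbols; a single symbol means the row
#                         reports plain gene-copy counts
#   keywords:             optional extra product-string search terms per
#                         symbol (case-insensitive substrings); the symbol
#                         itself is always searched
#   reference_proteins:   optional symbol -> seed amino-acid sequence for
#                         homology matching
#   min_fraction_present: fraction of symbols a cluster must cover (default 1.0)
#   max_gene_gap:         max gene-rank gap within a cluster (default 5)
modules:
  - module_id: mxaFJGI
    gene_symbols: [mxaF, mxaJ, mxaG, mxaI]
    keywords:
      mxaF: [mxaf, "methanol dehydrogenase large subunit"]
      mxaI: [mxai, "methanol dehydrogenase small subunit"]
      mxaG: [mxag, "methanol dehydrogenase cytochrome"]
      mxaJ: [mxaj]
  - module_id: xoxF
    gene_symbols: [xoxF]
    keywords:
      xoxF: [xoxf, "pqq-dependent dehydrogenase, methanol/ethanol family"]
  - module_id: mxaRSACKL
    gene_symbols: [mxaR, mxaS, mxaA, mxaC, mxaK, mxaL]
    min_fraction_present: 0.8
  - module_id: pqqA
    gene_symbols: [pqqA]
    keywords:
      pqqA: [pqqa, "pyrroloquinoline quinone precursor peptide"]
  - module_id: pqqBCDEFG
    gene_symbols: [pqqB, pqqC, pqqD, pqqE, pqqF, pqqG]
    min_fraction_present: 0.8
  - module_id: mau
    gene_symbols: [mauF, mauB, mauE, mauD, mauA, mauG, mauL, mauM, mauN]
    keywords:
      mauA: [maua, "methylamine dehydrogenase light chain"]
      mauB: [maub, "methylamine dehydrogenase heavy chain"]
    min_fraction_present: 0.8
  - module_id: n_methylglutamate
    gene_symbols: [mgdA, mgdB, mgdC, mgdD, gma, mgsA, mgsB, mgsC]
    min_fraction_present: 0.75
  - module_id: fae
    gene_symbols: [fae]
    keywords:
      fae: ["formaldehyde activating enzyme", fae]
  - module_id: fae2
    gene_symbols: [fae2]
  - module_id: fae3
    gene_symbols: [fae3]
  - module_id: h4mpt
    gene_symbols: [fhcA, fhcB, fhcC, fhcD, mptG, mtdB, mch]
    keywords:
      mch: [mch, methenyltetrahydromethanopterin]
    min_fraction_present: 0.7
    max_gene_gap: 8
  - module_id: fdh1
    gene_symbols: [fdh1A, fdh1B, fdh1C, fdh1D, fdh1E]
    min_fraction_present: 0.8
  - module_id: fdh4
    gene_symbols: [fdh4A, fdh4B]
  - module_id: rump
    gene_symbols: [hps, hpi, tal, pgi, zwf, pgl, edd, eda, tkt, rpe]
    keywords:
      hps: [hps, hexulose-6-phosphate synthase]
      hpi: [hpi, hexulosephosphate isomerase]
    min_fraction_present: 0.6
    max_gene_gap: 30
  - module_id: gndA
    gene_symbols: [gndA]
  - module_id: gndB
    gene_symbols: [gndB]
  - module_id: mcc
    gene_symbols: [prpC, prpB, prpD, prpE, fum, can]
    keywords:
      prpC: [prpc, methylcitrate synthase]
      prpB: [prpb, methylisocitrate lyase]
      prpD: [prpd, methylcitrate dehydratase]
    min_fraction_present: 0.6
    max_gene_gap: 10
  - module_id: nap
    gene_symbols: [nap]
    keywords:
      nap: [nap, "periplasmic nitrate reductase"]
  - module_id: narABC
    gene_symbols: [narA, narB, narC]
    keywords:
      narA: [nara, "respiratory nitrate reductase alpha"]
  - module_id: nirBD
    gene_symbols: [nirB, nirD]
    keywords:
      nirB: [nirb, "nitrite reductase (NADH) large subunit"]
      nirD: [nird, "nitrite reductase (NADH) small subunit"]
  - module_id: nirK
    gene_symbols: [nirK]
    keywords:
      nirK: [nirk, "copper-containing nitrite reductase"]
  - module_id: norBD
    gene_symbols: [norB, norD]
    keywords:
      norB: [norb, "nitric oxide reductase subunit b"]
    min_fraction_present: 0.5
  - module_id: nosZ
    gene_symbols: [nosZ]
    keywords:
      nosZ: [nosz, "nitrous oxide reductase"]
  - module_id: gs_gogat
    gene_symbols: [glnA, gltB, gltD]
    keywords:
      glnA: [glna, "glutamine synthetase"]
      gltB: [gltb, "glutamate synthase large"]
      gltD: [gltd, "glutamate synthase small"]
    min_fraction_present: 0.66
    max_gene_gap: 50
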