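# PTS motif table.
#
# pts1: accept-list of C-terminal tripeptides -> confidence tier.
#   canonical  classical [SA][KR][LMI]-family plus non-classical tripeptides
#              observed on curated peroxisomal matrix proteins
#   verified   experimentally validated non-classical signals
#   putative   predicted, not yet experimentally validated
# pts2: nonapeptide pattern R[LIQV]-x5-H[LF]; window = max 1-based start
#   offset of the frame from the N-terminus.
pts1:
  # classical consensus family
  SKL: canonical
  SKM: canonical
  SKI: canonical
  SRL: canonical
  SRM: canonical
  SRI: canonical
  AKL: canonical
  AKM: canonical
  AKI: canonical
  ARL: canonical
  ARM: canonical
  ARI: canonical
  # non-classical signals observed on peroxisomal matrix proteins
  SSL: canonical
  SSV: canonical
  TNL: canonical
  PRL: canonical
  PKL: canonical
  SAK: canonical
  SNM: canonical
  ANL: canonical
  ASL: canonical
  HKL: canonical
  QKL: canonical
  # experimentally verified non-classical signals
  VKL: verified
  PKI: verified
  # predicted, not yet validated
  HKN: putative
  KNI: putative
pts2:
  pos1: "R"
  pos2: "LIQV"
  pos8: "H"
  pos9: "LF"
  gap: 5
  window: 40
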