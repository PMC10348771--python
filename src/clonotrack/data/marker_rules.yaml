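# Default marker-gating rules for lineage assignment.
#
# A cell's score for a label is the mean normalized expression of the
# required-positive genes minus the mean of the required-negative genes.
# The label is the argmax over labels whose score meets the threshold;
# ties break by the priority order below.  Genes follow the canonical
# marker panel for kidney immune infiltrates (PTPRC for leukocytes, CD3E
# for T cells, CD8A/CD4/TRDC for T sublineages, CD19/MS4A1 for B cells,
# CD68/CD14/ITGAX for myeloid cells, EPCAM/KRT18 for epithelium).
priority: [CD8_T, CD4_T, gd_T, B, myeloid, nonimmune]
rules:
  CD8_T:
    positive: [CD3E, CD8A]
    negative: [CD4, TRDC, CD68, CD19, CD14, EPCAM]
    threshold: 0.1
  CD4_T:
    positive: [CD3E, CD4]
    negative: [CD8A, TRDC, CD68, CD19, CD14, EPCAM]
    threshold: 0.1
  gd_T:
    positive: [CD3E, TRDC]
    negative: [CD4, CD8A, CD68, CD19, CD14, EPCAM]
    threshold: 0.1
  B:
    positive: [CD19, MS4A1]
    negative: [CD3E, CD14, CD68, EPCAM]
    threshold: 0.1
  myeloid:
    positive: [CD68, CD14]
    negative: [CD3E, CD19, EPCAM]
    threshold: 0.1
  nonimmune:
    positive: [EPCAM, KRT18]
    negative: [PTPRC, CD3E]
    threshold: 0.1
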