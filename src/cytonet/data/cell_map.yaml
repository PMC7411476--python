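# Default cell-cytokine mapping: secretory cells and target cells for the
# 24-analyte rat cytokine panel, over a 28-cell roster (8 innate immune,
# 11 adaptive immune, 9 body cell types).
#
# SYNTHETIC / EDITORIAL RECONSTRUCTION. This table was compiled by the
# package authors from standard immunology references (Janeway-level
# textbook knowledge of which cell types produce and respond to each
# mediator). It is a documented default, not a measured dataset; users with
# their own curation should supply an override file in the same format.
cells:
  # innate immune cells
  - monocyte macrophages
  - neutrophils
  - dendritic cells
  - NK cells
  - NKT cells
  - mast cells
  - eosinophils
  - basophils
  # adaptive immune cells
  - CD4+ T cells
  - TH1 cells
  - TH2 cells
  - TH9 cells
  - TH17 cells
  - TH22 cells
  - Treg cells
  - CTL cells
  - Tr1 cells
  - B cells
  - plasma cells
  # body cells
  - endothelial cells
  - epithelial cells
  - fibroblast cells
  - keratinocyte cells
  - stromal cells
  - hypothalamic cells
  - liver cells
  - smooth muscle cells
  - adipocyte cells

secretors:
  "IL-1α": [monocyte macrophages, keratinocyte cells, epithelial cells, fibroblast cells]
  "IL-1β": [monocyte macrophages, neutrophils, dendritic cells, mast cells]
  "IL-6": [monocyte macrophages, fibroblast cells, endothelial cells, mast cells, TH2 cells, dendritic cells, adipocyte cells]
  "IL-7": [stromal cells, epithelial cells]
  "IL-18": [monocyte macrophages, dendritic cells, epithelial cells, keratinocyte cells]
  "TNF-α": [monocyte macrophages, mast cells, NK cells, TH1 cells, neutrophils]
  "CRP": [liver cells, epithelial cells, smooth muscle cells]
  "IL-2": [CD4+ T cells, TH1 cells]
  "IL-4": [TH2 cells, mast cells, basophils, NKT cells]
  "IL-5": [TH2 cells, mast cells, eosinophils]
  "IL-10": [Treg cells, Tr1 cells, TH2 cells, monocyte macrophages, B cells]
  "IL-12": [monocyte macrophages, dendritic cells, B cells]
  "IL-13": [TH2 cells, mast cells, basophils, NKT cells]
  "IL-17": [TH17 cells, NKT cells, neutrophils]
  "IFN-γ": [TH1 cells, NK cells, NKT cells, CTL cells]
  "MCP-1": [monocyte macrophages, endothelial cells, fibroblast cells, epithelial cells, smooth muscle cells]
  "CXCL1": [monocyte macrophages, epithelial cells, endothelial cells, fibroblast cells]
  "RANTES": [CTL cells, NK cells, epithelial cells, fibroblast cells, monocyte macrophages]
  "MIP-1α": [monocyte macrophages, neutrophils, dendritic cells, mast cells, NK cells]
  "MIP-3α": [epithelial cells, monocyte macrophages, dendritic cells, keratinocyte cells]
  "GM-CSF": [TH1 cells, TH17 cells, monocyte macrophages, mast cells, NK cells, fibroblast cells, endothelial cells]
  "G-CSF": [monocyte macrophages, fibroblast cells, endothelial cells, stromal cells]
  "M-CSF": [monocyte macrophages, fibroblast cells, endothelial cells, stromal cells, epithelial cells]
  "VEGF": [monocyte macrophages, fibroblast cells, keratinocyte cells, smooth muscle cells, mast cells, epithelial cells]

targets:
  "IL-1α": [endothelial cells, fibroblast cells, hypothalamic cells, epithelial cells, CD4+ T cells, monocyte macrophages]
  "IL-1β": [endothelial cells, fibroblast cells, hypothalamic cells, smooth muscle cells, CD4+ T cells, monocyte macrophages, liver cells]
  "IL-6": [liver cells, B cells, plasma cells, CD4+ T cells, TH22 cells, hypothalamic cells, fibroblast cells, endothelial cells]
  "IL-7": [CD4+ T cells, B cells, CTL cells, NKT cells]
  "IL-18": [NK cells, TH1 cells, CTL cells, monocyte macrophages]
  "TNF-α": [endothelial cells, fibroblast cells, monocyte macrophages, neutrophils, adipocyte cells, liver cells, hypothalamic cells]
  "CRP": [monocyte macrophages, neutrophils, endothelial cells]
  "IL-2": [CD4+ T cells, CTL cells, NK cells, Treg cells, B cells]
  "IL-4": [B cells, CD4+ T cells, TH2 cells, TH9 cells, monocyte macrophages, fibroblast cells]
  "IL-5": [eosinophils, B cells, basophils]
  "IL-10": [monocyte macrophages, dendritic cells, CD4+ T cells, B cells, mast cells]
  "IL-12": [TH1 cells, NK cells, NKT cells, CTL cells, CD4+ T cells]
  "IFN-γ": [monocyte macrophages, endothelial cells, epithelial cells, B cells, NK cells]
  "IL-13": [B cells, monocyte macrophages, epithelial cells, fibroblast cells, smooth muscle cells]
  "IL-17": [epithelial cells, endothelial cells, fibroblast cells, keratinocyte cells, monocyte macrophages, stromal cells]
  "MCP-1": [monocyte macrophages, NK cells, CD4+ T cells, dendritic cells, basophils]
  "CXCL1": [neutrophils, endothelial cells]
  "RANTES": [monocyte macrophages, NK cells, CD4+ T cells, eosinophils, basophils, dendritic cells, mast cells]
  "MIP-1α": [monocyte macrophages, neutrophils, NK cells, eosinophils, dendritic cells, CD4+ T cells]
  "MIP-3α": [dendritic cells, CD4+ T cells, B cells, TH17 cells]
  "GM-CSF": [monocyte macrophages, neutrophils, dendritic cells, eosinophils]
  "G-CSF": [neutrophils, stromal cells]
  "M-CSF": [monocyte macrophages, dendritic cells]
  "VEGF": [endothelial cells, monocyte macrophages, smooth muscle cells]
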