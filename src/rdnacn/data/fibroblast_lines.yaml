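# Five diploid human dermal fibroblast lines with their donors' leukocyte
# rDNA parameters and the passage-5 fibroblast measurements. The number in
# each line name is the final passage, after which division stopped.
lines:
  - name: HSF-45
    donor_age: 35
    final_passage: 45
    cn_leukocyte: 430
    cn_leukocyte_se: 50
    cn_fibroblast_p5: 450
    cn_fibroblast_p5_se: 40
    m_leukocyte: 1.1
    m_leukocyte_se: 0.2
    m_fibroblast_p5: 1.0
    m_fibroblast_p5_se: 0.1
  - name: HSF-53
    donor_age: 21
    final_passage: 53
    cn_leukocyte: 390
    cn_leukocyte_se: 40
    cn_fibroblast_p5: 370
    cn_fibroblast_p5_se: 20
    m_leukocyte: 1.0
    m_leukocyte_se: 0.1
    m_fibroblast_p5: 1.2
    m_fibroblast_p5_se: 0.2
  - name: HSF-57
    donor_age: 52
    final_passage: 57
    cn_leukocyte: 570
    cn_leukocyte_se: 30
    cn_fibroblast_p5: 590
    cn_fibroblast_p5_se: 40
    m_leukocyte: 2.1
    m_leukocyte_se: 0.2
    m_fibroblast_p5: 1.7
    m_fibroblast_p5_se: 0.2
  - name: HSF-61
    donor_age: 52
    final_passage: 61
    cn_leukocyte: 480
    cn_leukocyte_se: 40
    cn_fibroblast_p5: 470
    cn_fibroblast_p5_se: 60
    m_leukocyte: 1.2
    m_leukocyte_se: 0.1
    m_fibroblast_p5: 1.1
    m_fibroblast_p5_se: 0.2
  - name: HSF-66
    donor_age: 35
    final_passage: 66
    cn_leukocyte: 640
    cn_leukocyte_se: 40
    cn_fibroblast_p5: 670
    cn_fibroblast_p5_se: 70
    m_leukocyte: 2.2
    m_leukocyte_se: 0.2
    m_fibroblast_p5: 1.9
    m_fibroblast_p5_se: 0.2
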