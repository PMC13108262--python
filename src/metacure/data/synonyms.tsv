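variant	canonical
pbmc	blood
pbmcs	blood
peripheral blood mononuclear cells	blood
whole blood	blood
blood sample	blood
peripheral blood	blood
hcc	liver
hepatocellular carcinoma	liver
liver tissue	liver
lung tissue	lung
nsclc	lung
nsclc tumor	lung
ovarian tissue	ovary
ovarian tumor	ovary
ovarian cancer	ovary
plasma sample	plasma
plasma specimen	plasma
blood plasma	plasma
lymph node	lymph
lymph node biopsy	lymph
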