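# srtkit reference example list (published 20-sentence list definition)
list_number,sentence_number,template_id,offset_db
1,1134,4,-0.8
1,159,9,2.7
1,518,8,2.2
1,312,2,-0.7
1,1062,2,0.6
1,253,3,-0.4
1,955,5,-0.8
1,908,8,-1.8
1,496,6,-0.2
1,677,7,-0.6
1,121,1,0.3
1,100,10,-1.2
1,951,1,0.1
1,564,4,0.3
1,667,7,0.4
1,723,3,0.1
1,1069,9,-2.1
1,1120,10,1.6
1,255,5,0.8
1,326,6,0.3
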