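site,age_group,individuals,female,deaths_cvd,deaths_primary_cancer,deaths_any_cancer
bladder,40-59,1288,324,32,99,172
bladder,60-79,5640,1230,598,714,1316
bladder,80+,2080,594,367,384,600
breast,40-59,12208,12208,88,1486,1713
breast,60-79,12669,12669,661,1701,2304
breast,80+,3793,3793,646,879,1064
colorectal,40-59,3029,1364,29,690,856
colorectal,60-79,10029,4125,638,2189,3057
colorectal,80+,3471,1881,500,948,1304
leukemia,40-59,903,344,16,168,198
leukemia,60-79,2217,885,151,489,664
leukemia,80+,759,371,114,177,234
lung,40-59,1044,510,25,593,631
lung,60-79,4102,1723,183,2373,2544
lung,80+,1016,504,93,607,646
melanoma,40-59,2850,1673,12,200,256
melanoma,60-79,3396,1684,197,358,556
melanoma,80+,1030,599,158,122,229
nhl,40-59,1450,622,25,200,263
nhl,60-79,2674,1293,203,535,718
nhl,80+,721,418,114,188,250
prostate,40-59,2341,0,29,229,264
prostate,60-79,16742,0,1182,2647,3533
prostate,80+,4677,0,818,1271,1560
uterus,40-59,1133,1133,18,88,128
uterus,60-79,2328,2328,120,325,473
uterus,80+,438,438,74,98,133
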