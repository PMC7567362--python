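abbreviation,name,tissue,hemisphere,label
CSTl,Corticospinal Tract (left),WM,left,1
CSTr,Corticospinal Tract (right),WM,right,2
MLl,Medial Lemniscus (left),WM,left,3
MLr,Medial Lemniscus (right),WM,right,4
ICPl,Inferior Cerebellar Peduncle (left),WM,left,5
ICPr,Inferior Cerebellar Peduncle (right),WM,right,6
SCPl,Superior Cerebellar Peduncle (left),WM,left,7
SCPr,Superior Cerebellar Peduncle (right),WM,right,8
CPl,Cerebral Peduncle (left),WM,left,9
CPr,Cerebral Peduncle (right),WM,right,10
ALICl,Anterior Limb of Internal Capsule (left),WM,left,11
ALICr,Anterior Limb of Internal Capsule (right),WM,right,12
PLICl,Posterior Limb of Internal Capsule (left),WM,left,13
PLICr,Posterior Limb of Internal Capsule (right),WM,right,14
RLICl,Retrolenticular Limb of Internal Capsule (left),WM,left,15
RLICr,Retrolenticular Limb of Internal Capsule (right),WM,right,16
ACRl,Anterior Corona Radiata (left),WM,left,17
ACRr,Anterior Corona Radiata (right),WM,right,18
SCRl,Superior Corona Radiata (left),WM,left,19
SCRr,Superior Corona Radiata (right),WM,right,20
PCRl,Posterior Corona Radiata (left),WM,left,21
PCRr,Posterior Corona Radiata (right),WM,right,22
PTRl,Posterior Thalamic Radiation (left),WM,left,23
PTRr,Posterior Thalamic Radiation (right),WM,right,24
SSl,Sagittal Stratum (left),WM,left,25
SSr,Sagittal Stratum (right),WM,right,26
ECl,External Capsule (left),WM,left,27
ECr,External Capsule (right),WM,right,28
CGCl,Cingulum (Cingulate) (left),WM,left,29
CGCr,Cingulum (Cingulate) (right),WM,right,30
CGHl,Cingulum (Hippocampus) (left),WM,left,31
CGHr,Cingulum (Hippocampus) (right),WM,right,32
FXCl,Fornix (Cres) (left),WM,left,33
FXCr,Fornix (Cres) (right),WM,right,34
SLFl,Superior Longitudinal Fasciculus (left),WM,left,35
SLFr,Superior Longitudinal Fasciculus (right),WM,right,36
SFOl,Superior Fronto-Occipital Fasciculus (left),WM,left,37
SFOr,Superior Fronto-Occipital Fasciculus (right),WM,right,38
UFl,Uncinate Fasciculus (left),WM,left,39
UFr,Uncinate Fasciculus (right),WM,right,40
TAPl,Tapetum (left),WM,left,41
TAPr,Tapetum (right),WM,right,42
MCP,Middle Cerebellar Peduncle,WM,midline,43
PCT,Pontine Crossing Tract,WM,midline,44
GCC,Genu of Corpus Callosum,WM,midline,45
BCC,Body of Corpus Callosum,WM,midline,46
SCC,Splenium of Corpus Callosum,WM,midline,47
FX,Fornix,WM,midline,48
BA1l,Primary Somatosensory Cortex 1 (left),GM,left,101
BA1r,Primary Somatosensory Cortex 1 (right),GM,right,102
BA2l,Primary Somatosensory Cortex 2 (left),GM,left,103
BA2r,Primary Somatosensory Cortex 2 (right),GM,right,104
BA3l,Primary Somatosensory Cortex 3 (left),GM,left,105
BA3r,Primary Somatosensory Cortex 3 (right),GM,right,106
BA4l,Primary Motor Cortex (left),GM,left,107
BA4r,Primary Motor Cortex (right),GM,right,108
BA5l,Somatosensory Association Cortex (left),GM,left,109
BA5r,Somatosensory Association Cortex (right),GM,right,110
BA6l,Premotor and Supplementary Motor (left),GM,left,111
BA6r,Premotor and Supplementary Motor (right),GM,right,112
BA7l,Visuo-Motor Coordination (left),GM,left,113
BA7r,Visuo-Motor Coordination (right),GM,right,114
BA8l,Frontal Eye Fields (left),GM,left,115
BA8r,Frontal Eye Fields (right),GM,right,116
BA9l,Dorsolateral Prefrontal Cortex (left),GM,left,117
BA9r,Dorsolateral Prefrontal Cortex (right),GM,right,118
BA10l,Anterior Prefrontal Cortex (left),GM,left,119
BA10r,Anterior Prefrontal Cortex (right),GM,right,120
BA11l,Orbitofrontal Area (left),GM,left,121
BA11r,Orbitofrontal Area (right),GM,right,122
BA13l,Insular Cortex (left),GM,left,123
BA13r,Insular Cortex (right),GM,right,124
BA17l,Primary Visual Cortex (V1) (left),GM,left,125
BA17r,Primary Visual Cortex (V1) (right),GM,right,126
BA18l,Secondary Visual Cortex (V2) (left),GM,left,127
BA18r,Secondary Visual Cortex (V2) (right),GM,right,128
BA19l,Associative Visual Cortex (V3-5) (left),GM,left,129
BA19r,Associative Visual Cortex (V3-5) (right),GM,right,130
BA20l,Inferior Temporal Gyrus (left),GM,left,131
BA20r,Inferior Temporal Gyrus (right),GM,right,132
BA21l,Middle Temporal Gyrus (left),GM,left,133
BA21r,Middle Temporal Gyrus (right),GM,right,134
BA22l,Superior Temporal Gyrus (left),GM,left,135
BA22r,Superior Temporal Gyrus (right),GM,right,136
BA23l,Ventral Posterior Cingulate Cortex (left),GM,left,137
BA23r,Ventral Posterior Cingulate Cortex (right),GM,right,138
BA24l,Ventral Anterior Cingulate Cortex (left),GM,left,139
BA24r,Ventral Anterior Cingulate Cortex (right),GM,right,140
BA25l,Subgenual Area (left),GM,left,141
BA25r,Subgenual Area (right),GM,right,142
BA26l,Ectosplenial Portion of Retrosplenial Region (left),GM,left,143
BA26r,Ectosplenial Portion of Retrosplenial Region (right),GM,right,144
BA27l,Piriform Cortex (left),GM,left,145
BA27r,Piriform Cortex (right),GM,right,146
BA28l,Ventral Entorhinal Cortex (left),GM,left,147
BA28r,Ventral Entorhinal Cortex (right),GM,right,148
BA29l,Retrosplenial Cingulate Cortex (left),GM,left,149
BA29r,Retrosplenial Cingulate Cortex (right),GM,right,150
BA30l,Part of Cingulate Cortex (left),GM,left,151
BA30r,Part of Cingulate Cortex (right),GM,right,152
BA32l,Dorsal Anterior Cingulate Cortex (left),GM,left,153
BA32r,Dorsal Anterior Cingulate Cortex (right),GM,right,154
BA34l,Dorsal Entorhinal Cortex (left),GM,left,155
BA34r,Dorsal Entorhinal Cortex (right),GM,right,156
BA35l,Perirhinal Cortex (left),GM,left,157
BA35r,Perirhinal Cortex (right),GM,right,158
BA36l,Ectorhinal Area (left),GM,left,159
BA36r,Ectorhinal Area (right),GM,right,160
BA37l,Occipitotemporal Area (left),GM,left,161
BA37r,Occipitotemporal Area (right),GM,right,162
BA38l,Temporopolar Area (left),GM,left,163
BA38r,Temporopolar Area (right),GM,right,164
BA39l,Angular Gyrus (left),GM,left,165
BA39r,Angular Gyrus (right),GM,right,166
BA40l,Supramarginal Gyrus (left),GM,left,167
BA40r,Supramarginal Gyrus (right),GM,right,168
BA41l,Auditory Cortex 1 (left),GM,left,169
BA41r,Auditory Cortex 1 (right),GM,right,170
BA42l,Auditory Cortex 2 (left),GM,left,171
BA42r,Auditory Cortex 2 (right),GM,right,172
BA43l,Primary Gustatory Cortex (left),GM,left,173
BA43r,Primary Gustatory Cortex (right),GM,right,174
BA44l,Pars Opercularis (left),GM,left,175
BA44r,Pars Opercularis (right),GM,right,176
BA45l,Pars Triangularis (left),GM,left,177
BA45r,Pars Triangularis (right),GM,right,178
BA46l,Dorsolateral Prefrontal Cortex (left),GM,left,179
BA46r,Dorsolateral Prefrontal Cortex (right),GM,right,180
BA47l,Pars Orbitalis (left),GM,left,181
BA47r,Pars Orbitalis (right),GM,right,182
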