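mirna_id	c14mc	c19mc	whole_plasma_log2fc	whole_plasma_p	ev_log2fc	ev_p	ev_depleted_log2fc	ev_depleted_p
hsa‐miR‐100‐5p					−0.82	4.63E−02		
hsa‐miR‐1‐1‐3p			−0.86	1.76E−02				
hsa‐miR‐1179‐5p			−0.83	3.94E−06				
hsa‐miR‐1185‐1‐3p	X		−0.82	3.02E−03				
hsa‐miR‐1185‐1‐5p	X		−0.95	1.76E−04				
hsa‐miR‐1185‐2‐3p	X		−0.72	2.29E−03				
hsa‐miR‐1246‐5p			2.10	3.90E−07				
hsa‐miR‐1249‐3p			−1.23	3.81E−04			−1.04	3.46E−02
hsa‐miR‐1256‐3p			−0.61	4.34E−03				
hsa‐miR‐126‐3p			−0.63	1.09E−03				
hsa‐miR‐126‐5p			−0.62	5.66E−04				
hsa‐miR‐127‐3p	X		−0.97	1.53E−03				
hsa‐miR‐127‐5p	X		−0.75	1.16E−02	−0.94	1.91E−02		
hsa‐miR‐1277‐3p			−1.42	5.46E−09				
hsa‐miR‐1277‐5p			−1.20	3.42E−06				
hsa‐miR‐130a‐3p			−0.69	2.10E−03				
hsa‐miR‐130a‐5p			−0.62	1.15E−03				
hsa‐miR‐1343‐3p			−0.68	4.79E−03				
hsa‐miR‐135a‐1‐5p			−1.06	7.26E−06				
hsa‐miR‐136‐3p	X		−0.68	2.40E−02	−0.83	1.66E−02		
hsa‐miR‐136‐5p	X		−0.84	6.39E−03			−1.14	5.38E−03
hsa‐miR‐141‐3p					−0.81	7.49E−03		
hsa‐miR‐142‐3p			−0.65	1.94E−03				
hsa‐miR‐146b‐5p			−0.69	8.22E−05				
hsa‐miR‐153‐1‐3p			−0.61	5.55E−04				
hsa‐miR‐154‐3p	X		−0.75	3.77E−03			−0.92	4.46E−02
hsa‐miR‐154‐5p	X		−0.69	7.13E−03				
hsa‐miR‐155‐5p			−0.69	6.57E−04				
hsa‐miR‐181b‐2‐5p			−0.61	4.16E−04				
hsa‐miR‐181c‐3p			−0.66	3.01E−03				
hsa‐miR‐181c‐5p			−0.96	1.63E−06				
hsa‐miR‐181d‐5p			−0.77	1.98E−04				
hsa‐miR‐183‐5p			0.63	1.69E−03				
hsa‐miR‐186‐3p			−0.84	3.06E−04				
hsa‐miR‐192‐5p					0.71	2.26E−02		
hsa‐miR‐193a‐5p			0.96	9.50E−05				
hsa‐miR‐193b‐3p			0.70	1.60E−02				
hsa‐miR‐194‐1‐5p					0.63	3.55E−02		
hsa‐miR‐199a‐1‐5p			−0.89	7.18E−05				
hsa‐miR‐19b‐2‐3p			−0.72	2.15E−05				
hsa‐miR‐20a‐3p			−0.85	6.27E−06				
hsa‐miR‐214‐3p					0.69	4.40E−02		
hsa‐miR‐215‐5p			−0.79	2.07E−02				
hsa‐miR‐219a‐1‐5p			−0.84	1.37E−05				
hsa‐miR‐221‐3p			−0.61	6.16E−04				
hsa‐miR‐26a‐1‐5p			−0.76	1.17E−04				
hsa‐miR‐26a‐2‐3p			−0.60	2.91E−04				
hsa‐miR‐26b‐5p			−0.80	9.30E−06				
hsa‐miR‐299‐3p	X		−0.64	2.17E−02				
hsa‐miR‐299‐5p	X		−0.81	2.25E−03			−0.82	1.79E−02
hsa‐miR‐29a‐5p			−0.62	4.49E−04				
hsa‐miR‐29b‐2‐3p			−1.11	2.93E−07				
hsa‐miR‐301a‐3p			−0.87	3.85E−07				
hsa‐miR‐301b‐3p			−0.85	2.64E−05				
hsa‐miR‐30d‐3p			−0.61	5.87E−03				
hsa‐miR‐32‐3p			−0.75	8.85E−05				
hsa‐miR‐324‐5p			−0.62	1.07E−03				
hsa‐miR‐328‐3p			−0.77	1.29E−03				
hsa‐miR‐331‐3p			−0.74	1.09E−03				
hsa‐miR‐335‐3p			−0.82	4.57E−04				
hsa‐miR‐337‐3p	X		−0.71	1.83E−02	−0.83	1.91E−02		
hsa‐miR‐337‐5p	X		−0.69	2.41E−02	−0.87	4.76E−03		
hsa‐miR‐338‐3p			−0.80	5.37E−04			−0.86	4.24E−02
hsa‐miR‐33a‐3p					−0.67	2.14E−02		
hsa‐miR‐33a‐5p			−0.67	1.52E−02				
hsa‐miR‐340‐5p			−0.75	1.07E−04				
hsa‐miR‐3611‐3p			−0.73	1.13E−03				
hsa‐miR‐3617‐5p			−0.85	1.32E−04				
hsa‐miR‐365a‐3p			0.60	6.57E−03				
hsa‐miR‐3667‐5p			−0.67	2.29E−02				
hsa‐miR‐369‐3p	X		−0.68	1.90E−02	−0.96	7.59E−03		
hsa‐miR‐369‐5p	X		−0.63	2.48E−02	−0.90	2.78E−02		
hsa‐miR‐370‐3p			−0.81	8.12E−03				
hsa‐miR‐374a‐5p			−0.93	2.39E−06				
hsa‐miR‐374b‐3p			−0.79	9.37E−05				
hsa‐miR‐374b‐5p			−0.79	4.16E−05				
hsa‐miR‐376a‐1‐3p	X		−0.70	8.44E−03				
hsa‐miR‐376a‐1‐5p	X		−0.90	2.51E−04				
hsa‐miR‐376b‐3p	X		−1.01	1.19E−03	−0.71	2.75E−02		
hsa‐miR‐376c‐3p	X		−0.66	2.17E−02	−0.80	1.85E−02		
hsa‐miR‐376c‐5p	X		−1.32	1.58E−03				
hsa‐miR‐377‐3p	X		−0.82	1.26E−02	−0.89	5.77E−03	−1.19	1.46E−02
hsa‐miR‐378c‐5p					0.70	8.26E−04		
hsa‐miR‐379‐3p	X		−0.80	4.61E−03	−0.83	4.30E−02		
hsa‐miR‐379‐5p	X		−0.73	2.04E−02	−0.82	3.12E−02		
hsa‐miR‐380‐3p	X		−0.66	1.45E−02	−1.08	3.48E−03		
hsa‐miR‐381‐3p	X		−0.72	9.41E−03				
hsa‐miR‐382‐3p	X				−0.80	3.11E−02		
hsa‐miR‐409‐5p	X		−0.81	2.53E−03				
hsa‐miR‐410‐3p	X				−0.77	1.54E−02		
hsa‐miR‐411‐3p	X		−0.72	1.34E−02				
hsa‐miR‐411‐5p	X		−0.64	1.86E−02	−0.84	3.90E−02		
hsa‐miR‐421‐5p			−0.61	3.33E−03				
hsa‐miR‐431‐3p	X		−0.63	1.04E−02				
hsa‐miR‐431‐5p	X		−0.67	3.01E−02	−0.70	4.89E−02		
hsa‐miR‐432‐3p	X		−0.68	4.51E−03				
hsa‐miR‐4326‐5p					0.66	1.01E−02		
hsa‐miR‐450a‐1‐5p			−0.61	4.93E−03				
hsa‐miR‐4532‐5p			0.84	4.07E−02				
hsa‐miR‐454‐3p			−0.64	9.36E−05				
hsa‐miR‐4732‐5p			0.76	1.15E−05				
hsa‐miR‐483‐5p			1.18	5.55E−04			1.33	1.08E−02
hsa‐miR‐485‐3p	X		−0.66	1.90E−02				
hsa‐miR‐486‐1‐5p			0.75	9.07E−06			0.63	3.05E−02
hsa‐miR‐487a‐3p	X		−0.77	6.01E−03				
hsa‐miR‐487b‐3p	X		−0.68	1.38E−02	−0.67	4.82E−02		
hsa‐miR‐487b‐5p	X						−0.83	2.40E−02
hsa‐miR‐491‐5p			−0.74	8.20E−04				
hsa‐miR‐493‐3p	X		−0.74	1.01E−02				
hsa‐miR‐493‐5p	X		−0.72	1.08E−02				
hsa‐miR‐494‐3p	X		−0.76	7.83E−03				
hsa‐miR‐495‐3p	X		−0.75	8.20E−03	−0.67	4.24E−02		
hsa‐miR‐495‐5p	X		−0.64	9.50E−03				
hsa‐miR‐505‐5p					0.61	1.36E−02		
hsa‐miR‐512‐1‐5p		X			−0.85	4.14E−02		
hsa‐miR‐515‐1‐3p		X			−0.82	2.35E−02		
hsa‐miR‐515‐1‐5p		X			−0.97	2.45E−02		
hsa‐miR‐516b‐1‐5p		X			−0.91	3.62E−02		
hsa‐miR‐517a‐3p		X			−0.96	1.90E−02		
hsa‐miR‐517c‐3p		X			−1.04	1.92E−02		
hsa‐miR‐518b‐3p		X			−1.19	1.50E−02		
hsa‐miR‐518c‐3p		X			−1.03	4.42E−02		
hsa‐miR‐518f‐3p		X			−0.94	2.25E−02		
hsa‐miR‐518f‐5p		X	1.39	1.15E−03				
hsa‐miR‐5193‐3p			−0.64	2.46E−03				
hsa‐miR‐519d‐3p		X			−0.95	3.93E−02		
hsa‐miR‐520a‐3p		X	0.66	1.61E−02				
hsa‐miR‐520d‐5p		X			−1.01	8.36E−03		
hsa‐miR‐524‐5p		X			−0.94	4.56E−02		
hsa‐miR‐525‐5p		X			−1.26	1.22E−02		
hsa‐miR‐526b‐5p		X			−0.79	4.88E−02		
hsa‐miR‐539‐3p	X		−0.84	3.66E−03	−0.92	1.22E−02		
hsa‐miR‐545‐5p			−0.79	2.36E−05				
hsa‐miR‐548a‐1‐3p			−0.76	8.36E−03				
hsa‐miR‐548a‐3‐5p			−0.71	2.35E−03				
hsa‐miR‐548ax‐3p			−0.68	1.47E−03				
hsa‐miR‐548ax‐5p			−0.79	7.02E−04				
hsa‐miR‐551b‐3p			−0.71	2.24E−03	−0.74	1.45E−02		
hsa‐miR‐556‐3p			−0.73	6.56E−04				
hsa‐miR‐556‐5p			−0.85	4.70E−04				
hsa‐miR‐582‐5p			0.61	2.23E−02				
hsa‐miR‐589‐3p					0.71	2.26E−03		
hsa‐miR‐590‐3p			−1.25	6.34E−07	−0.68	2.98E−02		
hsa‐miR‐590‐5p			−0.76	4.93E−05				
hsa‐miR‐625‐5p			−0.61	2.70E−03				
hsa‐miR‐627‐3p			−0.63	3.78E−03				
hsa‐miR‐628‐5p			−0.75	2.27E−06				
hsa‐miR‐6516‐5p			−0.67	1.47E−03				
hsa‐miR‐654‐3p	X		−0.63	3.71E−02				
hsa‐miR‐655‐3p	X		−0.69	1.30E−02	−0.91	8.58E−03		
hsa‐miR‐656‐3p	X				−1.01	4.12E−03		
hsa‐miR‐664a‐3p			−0.66	5.82E−05				
hsa‐miR‐671‐5p			−0.64	2.55E−03	0.74	1.23E−02		
hsa‐miR‐6741‐3p			−0.62	1.52E−03				
hsa‐miR‐744‐3p			−0.65	1.24E−03				
hsa‐miR‐758‐3p	X		−0.91	4.00E−03				
hsa‐mir‐7641‐2					0.65	6.42E−03		
hsa‐miR‐877‐3p			−0.62	1.14E−02				
hsa‐miR‐889‐3p	X		−0.60	2.98E−02	−0.68	3.14E−02		
hsa‐miR‐92a‐2‐3p					0.73	9.10E−03		
hsa‐miR‐99b‐3p			−0.60	1.25E−02				
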